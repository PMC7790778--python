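"""Parameter sweeps quantifying the privacy/utility trade-off.

The sensitivity analyses vary each engine's control parameter — the
suppression threshold k (3, 5, 7, 9), the kNN cluster size k (5, 10, 20, 50)
and the noise fraction q (0.1, 0.5, 1, sqrt(2)) — across sample sizes
(50, 100, 300, 500 by default) with replicated synthetic datasets.

Because the underlying comparisons are visual, the utility loss is quantified
here by five scalar metrics (NaN where a metric does not apply to a method):

``suppressed_fraction``
    share of observations falling in suppressed grid cells (k-anon only);
    larger means more of the sample is simply missing from the plot.
``slope_deviation``
    |anonymized trend slope - raw trend slope|; for k-anon the anonymized
    trend is the count-weighted fit through surviving cell centers.
``range_shrinkage``
    ratio of the box-plot whisker span of the protected values to the raw
    whisker span, averaged over X and Y; below 1 the display understates the
    variable's range, above 1 it overstates it.
``distinct_centroids``
    number of distinct plotted positions after deterministic anonymization
    (coincident centroids collapse, so this is at most n).
``grid_l1``
    half the L1 distance between the displayed 2-D density grid and the raw
    grid on the raw grid's cells, divided by n; 0 means identical density
    surfaces, 1 means complete displacement.

Each sweep row is reproducible: the replicate's dataset seed is derived from
(base seed, sample size, replicate index) via a SeedSequence, independent of
execution order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import synthgen
from .anonymize import (
    PointCloud,
    SecretSeed,
    bin_series,
    deterministic_anonymize,
    generalize,
    grid_density,
    observation_cells,
    probabilistic_anonymize,
    suppress,
)
from .errors import ValidationError
from .plotdata import boxplot_payload, trend_line

logger = logging.getLogger(__name__)

SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class SweepConfig:
    """Grid of conditions for :func:`run_sweep`."""

    dataset: str = "D1"
    kanon_thresholds: tuple = (3, 5, 7, 9)
    det_ks: tuple = (5, 10, 20, 50)
    qs: tuple = (0.1, 0.5, 1.0, SQRT2)
    ns: tuple = (50, 100, 300, 500)
    replicates: int = 10
    base_seed: int = 1234
    grid: tuple = (30, 30)
    methods: tuple = ("kanon", "det", "prob")

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        for vals, label in (
            (self.kanon_thresholds, "kanon_thresholds"),
            (self.det_ks, "det_ks"),
            (self.qs, "qs"),
            (self.ns, "ns"),
        ):
            if any(v <= 0 for v in vals):
                raise ValidationError(f"all {label} values must be positive")


def _replicate_seed(base_seed: int, n: int, rep: int) -> int:
    ss = np.random.SeedSequence([base_seed, n, rep])
    return int(ss.generate_state(1)[0] % (2**31))


def _whisker_span(stats) -> float:
    return stats.whisker_high - stats.whisker_low


def _range_shrinkage(anon_cloud: PointCloud, raw_cloud: PointCloud) -> float:
    ratios = []
    for av, rv in ((anon_cloud.x, raw_cloud.x), (anon_cloud.y, raw_cloud.y)):
        a = boxplot_payload(av, "raw")
        r = boxplot_payload(rv, "raw")
        ratios.append(_whisker_span(a) / _whisker_span(r))
    return float(np.mean(ratios))


def _grid_l1(anon_cloud: PointCloud, raw_grid) -> float:
    """Half-L1 distance between the anonymized and raw density grids, per observation.

    The anonymized points are counted on the raw grid's edges; points escaping
    the raw span count fully toward displacement.
    """
    ex, ey = raw_grid.x_spec.edges, raw_grid.y_spec.edges
    cx = np.clip(np.searchsorted(ex, anon_cloud.x, side="right") - 1, -1, len(ex) - 2)
    inside_x = (anon_cloud.x >= ex[0]) & (anon_cloud.x <= ex[-1])
    cx[anon_cloud.x == ex[-1]] = len(ex) - 2
    cy = np.clip(np.searchsorted(ey, anon_cloud.y, side="right") - 1, -1, len(ey) - 2)
    inside_y = (anon_cloud.y >= ey[0]) & (anon_cloud.y <= ey[-1])
    cy[anon_cloud.y == ey[-1]] = len(ey) - 2
    inside = inside_x & inside_y
    counts = np.zeros_like(raw_grid.counts)
    np.add.at(counts, (cx[inside], cy[inside]), 1)
    n = len(anon_cloud)
    escaped = n - int(inside.sum())
    l1 = np.abs(counts - raw_grid.counts).sum() + escaped
    return float(l1 / (2.0 * n))


def _kanon_row(cloud: PointCloud, threshold: int, grid_shape: tuple) -> dict:
    grid = suppress(grid_density(cloud, *grid_shape), threshold)
    cells = observation_cells(cloud, grid)
    in_suppressed = grid.suppressed[cells[:, 0], cells[:, 1]]
    n = len(cloud)
    surviving = (grid.counts > 0) & ~grid.suppressed
    ix, iy = np.nonzero(surviving)
    row = {"suppressed_fraction": float(in_suppressed.sum() / n)}
    raw_b0, raw_b1 = trend_line(cloud.x, cloud.y)
    if len(ix) >= 2 and len(np.unique(grid.x_spec.centers[ix])) >= 2:
        _, b1 = trend_line(
            grid.x_spec.centers[ix],
            grid.y_spec.centers[iy],
            weights=grid.counts[ix, iy].astype(float),
        )
        row["slope_deviation"] = abs(b1 - raw_b1)
    else:
        row["slope_deviation"] = np.nan
    keep = ~in_suppressed
    if keep.sum() >= 5:
        row["range_shrinkage"] = _range_shrinkage(
            PointCloud(cloud.x[keep], cloud.y[keep]), cloud
        )
    else:
        row["range_shrinkage"] = np.nan
    displayed = grid.counts * ~grid.suppressed
    row["grid_l1"] = float(np.abs(displayed - grid.counts).sum() / (2.0 * n))
    row["distinct_centroids"] = np.nan
    return row


def _det_row(cloud: PointCloud, k: int, grid_shape: tuple) -> dict:
    anon = deterministic_anonymize(cloud, k)
    anon_cloud = PointCloud(anon.x, anon.y)
    raw_b0, raw_b1 = trend_line(cloud.x, cloud.y)
    _, b1 = trend_line(anon.x, anon.y)
    return {
        "suppressed_fraction": np.nan,
        "slope_deviation": abs(b1 - raw_b1),
        "range_shrinkage": _range_shrinkage(anon_cloud, cloud),
        "distinct_centroids": float(len(np.unique(np.column_stack([anon.x, anon.y]), axis=0))),
        "grid_l1": _grid_l1(anon_cloud, grid_density(cloud, *grid_shape)),
    }


def _prob_row(cloud: PointCloud, q: float, seed: int, grid_shape: tuple) -> dict:
    secret = SecretSeed(f"sweep-{seed}")
    noisy = probabilistic_anonymize(cloud, q, secret)
    anon_cloud = PointCloud(noisy.x, noisy.y)
    raw_b0, raw_b1 = trend_line(cloud.x, cloud.y)
    _, b1 = trend_line(noisy.x, noisy.y)
    var_ratio = float(
        np.mean(
            [
                noisy.x.var(ddof=1) / cloud.x.var(ddof=1),
                noisy.y.var(ddof=1) / cloud.y.var(ddof=1),
            ]
        )
    )
    return {
        "suppressed_fraction": np.nan,
        "slope_deviation": abs(b1 - raw_b1),
        "range_shrinkage": _range_shrinkage(anon_cloud, cloud),
        "distinct_centroids": np.nan,
        "grid_l1": _grid_l1(anon_cloud, grid_density(cloud, *grid_shape)),
        "var_ratio": var_ratio,
    }


def run_sweep(config: SweepConfig) -> pd.DataFrame:
    """Run the full sweep; one tidy row per (method, parameter, n, replicate).

    Infeasible combinations (kNN cluster size exceeding the sample size) are
    skipped with a logged warning.
    """
    rows = []
    param_grid = {
        "kanon": config.kanon_thresholds,
        "det": config.det_ks,
        "prob": config.qs,
    }
    for n in config.ns:
        for rep in range(config.replicates):
            seed = _replicate_seed(config.base_seed, n, rep)
            table = synthgen.generate(synthgen.DatasetSpec(config.dataset, n, seed))
            cloud = PointCloud.from_table(table)
            for method in config.methods:
                for param in param_grid[method]:
                    if method == "det" and param > n:
                        logger.warning(
                            "skipping infeasible combination: kNN k=%s > n=%s", param, n
                        )
                        continue
                    if method == "kanon":
                        metrics = _kanon_row(cloud, int(param), config.grid)
                    elif method == "det":
                        metrics = _det_row(cloud, int(param), config.grid)
                    else:
                        metrics = _prob_row(cloud, float(param), seed, config.grid)
                    rows.append(
                        {"method": method, "param": param, "n": n, "replicate": rep, "seed": seed}
                        | metrics
                    )
    return pd.DataFrame(rows)


def doubled_generalization(config: SweepConfig, hist_width: float = 0.2) -> pd.DataFrame:
    """Paired k-anonymization metrics at base and doubled generalization.

    For every (threshold, n, replicate) the grid metrics are computed on the
    base grid (default 30x30) and on the coarser grid with half as many cells
    per side (e.g. 15x15), and histogram suppression on the X variable is
    compared between bins of width *hist_width* and 2 * *hist_width*.  Rows
    are labelled ``level`` in {"base", "doubled"}.
    """
    gx, gy = config.grid
    rows = []
    for n in config.ns:
        for rep in range(config.replicates):
            seed = _replicate_seed(config.base_seed, n, rep)
            table = synthgen.generate(synthgen.DatasetSpec(config.dataset, n, seed))
            cloud = PointCloud.from_table(table)
            for threshold in config.kanon_thresholds:
                for level, shape, width in (
                    ("base", (gx, gy), hist_width),
                    ("doubled", (max(1, gx // 2), max(1, gy // 2)), 2 * hist_width),
                ):
                    metrics = _kanon_row(cloud, int(threshold), shape)
                    hist = suppress(bin_series(cloud.x, width=width), int(threshold))
                    occupied = hist.counts > 0
                    metrics["hist_nbins"] = hist.spec.nbins
                    metrics["hist_suppressed_fraction"] = float(
                        hist.counts[hist.suppressed].sum() / max(1, hist.counts.sum())
                    )
                    rows.append(
                        {
                            "method": "kanon",
                            "param": threshold,
                            "n": n,
                            "replicate": rep,
                            "seed": seed,
                            "level": level,
                        }
                        | metrics
                    )
    return pd.DataFrame(rows)
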