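"""Renderer-agnostic payloads for the privacy-preserving plot catalogue.

Each builder applies one of the three disclosure-control engines and returns
a payload object holding exactly the coordinates, counts and masks a renderer
needs — nothing else.  Serialized payloads (``to_dict``) withhold the counts
of suppressed cells entirely; masked positions carry ``None``.

Method tags used throughout:

``raw``
    no protection (for comparison only);
``suppress`` / ``generalize``
    the k-anonymization family: bin/grid the raw observations, optionally
    coarsen, then mask cells with non-zero count below the threshold;
``det``
    kNN-centroid anonymization of the values, then ordinary binning;
``prob``
    additive-noise anonymization of the values, then ordinary binning.

Density grids built from det/prob-anonymized points are displayed in full,
without further suppression: the plotted units are already anonymized values,
not raw observations.  This is a policy choice; the audit module still
reports small cells on such grids as warnings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .anonymize import (
    BinnedSeries,
    CentroidCloud,
    DensityGrid,
    NoisyCloud,
    PointCloud,
    SecretSeed,
    bin_series,
    deterministic_anonymize,
    deterministic_anonymize_series,
    generalize,
    grid_density,
    observation_cells,
    probabilistic_anonymize,
    suppress,
)
from .errors import ValidationError

KANON_METHODS = ("raw", "suppress", "generalize")
ANON_METHODS = ("det", "prob")


def _masked_list(values, mask):
    return [None if m else v for v, m in zip(np.asarray(values).tolist(), mask)]


def trend_line(x, y, weights=None) -> tuple:
    """(intercept, slope) of a least-squares line; weighted if *weights* given."""
    X = sm.add_constant(np.asarray(x, dtype=float))
    model = sm.WLS(np.asarray(y, dtype=float), X, weights=weights) if weights is not None else sm.OLS(
        np.asarray(y, dtype=float), X
    )
    b0, b1 = model.fit().params
    return float(b0), float(b1)


# ---------------------------------------------------------------------------
# histogram
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HistogramPayload:
    """Frequency-density histogram with suppression mask.

    The ordinate is frequency density (count / bin width), so for every
    unsuppressed bin density * width recovers the integer count exactly.
    """

    binned: BinnedSeries
    method: str
    params: dict

    @property
    def density(self) -> np.ndarray:
        return self.binned.counts / self.binned.spec.widths

    def to_dict(self) -> dict:
        mask = self.binned.suppressed
        return {
            "kind": "histogram",
            "method": self.method,
            "params": dict(self.params),
            "edges": self.binned.spec.edges.tolist(),
            "counts": _masked_list(self.binned.counts, mask),
            "density": _masked_list(self.density, mask),
            "mask": mask.tolist(),
        }


def histogram_payload(
    values,
    *,
    width: float | None = None,
    nbins: int | None = None,
    method: str = "raw",
    threshold: int = 3,
    generalize_factor: int = 2,
    k: int = 3,
    q: float = 0.25,
    secret: SecretSeed | None = None,
) -> HistogramPayload:
    """Build a privacy-preserving histogram payload of a single variable.

    For the k-anonymization family the raw values are binned first, then
    generalized and/or suppressed; for ``det``/``prob`` the values are
    anonymized first and then binned normally.
    """
    values = np.asarray(values, dtype=np.float64)
    if method == "raw":
        binned = bin_series(values, width=width, nbins=nbins)
        params = {}
    elif method == "suppress":
        binned = suppress(bin_series(values, width=width, nbins=nbins), threshold)
        params = {"threshold": threshold}
    elif method == "generalize":
        binned = bin_series(values, width=width, nbins=nbins)
        binned = suppress(generalize(binned, generalize_factor), threshold)
        params = {"threshold": threshold, "generalize_factor": generalize_factor}
    elif method == "det":
        anon = deterministic_anonymize_series(values, k)
        binned = bin_series(anon, width=width, nbins=nbins)
        params = {"k": k}
    elif method == "prob":
        if secret is None:
            raise ValidationError("probabilistic method requires a SecretSeed")
        anon = probabilistic_anonymize(values, q, secret)
        binned = bin_series(anon.values, width=width, nbins=nbins)
        params = {"q": q}
    else:
        raise ValidationError(f"unknown method {method!r}")
    return HistogramPayload(binned, method, params)


# ---------------------------------------------------------------------------
# scatter
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SizedDotPayload:
    """k-anonymized scatter: one dot per surviving grid cell.

    Dots sit at cell centers, sized by their cell count; every dot count is at
    least the suppression threshold.  ``hidden_fraction`` is the share of
    observations not individually visible: those in suppressed cells plus the
    per-cell aggregation excess (count - 1 per surviving cell).
    """

    grid: DensityGrid
    dots: np.ndarray  # (m, 3) columns: x center, y center, count
    threshold: int
    generalize_factor: int
    trend_raw: tuple
    trend_weighted: tuple | None
    hidden_fraction: float
    method: str = "kanon"

    def to_dict(self) -> dict:
        return {
            "kind": "sized-dot-scatter",
            "method": self.method,
            "params": {
                "threshold": self.threshold,
                "generalize_factor": self.generalize_factor,
            },
            "x_edges": self.grid.x_spec.edges.tolist(),
            "y_edges": self.grid.y_spec.edges.tolist(),
            "dots": [[float(a), float(b), int(c)] for a, b, c in self.dots],
            "mask": self.grid.suppressed.tolist(),
            "trend_raw": list(self.trend_raw),
            "trend_weighted": list(self.trend_weighted) if self.trend_weighted else None,
            "hidden_fraction": self.hidden_fraction,
        }


def scatter_kanon_payload(
    cloud: PointCloud,
    gx: int = 30,
    gy: int = 30,
    threshold: int = 3,
    generalize_factor: int = 1,
) -> SizedDotPayload:
    """Aggregate a point cloud on a grid, suppress small cells, dot the survivors.

    The weighted trend line is a least-squares fit through the surviving cell
    centers weighted by their counts; the raw trend (from the unprotected
    cloud) is carried alongside for utility comparison.
    """
    if threshold < 1:
        raise ValidationError("threshold must be >= 1")
    grid = grid_density(cloud, gx, gy)
    if generalize_factor > 1:
        grid = generalize(grid, generalize_factor)
    grid = suppress(grid, threshold)
    surviving = (grid.counts > 0) & ~grid.suppressed
    ix, iy = np.nonzero(surviving)
    cxs = grid.x_spec.centers[ix]
    cys = grid.y_spec.centers[iy]
    cnts = grid.counts[ix, iy]
    dots = np.column_stack([cxs, cys, cnts])
    n = len(cloud)
    hidden = float((n - len(dots)) / n)
    raw_trend = trend_line(cloud.x, cloud.y)
    if len(dots) == 0:
        warnings.warn("all cells suppressed: payload is empty", stacklevel=2)
        weighted = None
    elif len(np.unique(cxs)) < 2:
        weighted = None
    else:
        weighted = trend_line(cxs, cys, weights=cnts.astype(float))
    return SizedDotPayload(
        grid, dots, threshold, generalize_factor, raw_trend, weighted, hidden
    )


@dataclass(frozen=True)
class AnonScatterPayload:
    """Scatter of det/prob-anonymized points, with trend lines for utility reporting.

    For the deterministic method, ``multiplicity`` marks coincident centroids
    (the black-dot positions); for the probabilistic method it is all ones.
    """

    x: np.ndarray
    y: np.ndarray
    method: str
    params: dict
    multiplicity: np.ndarray
    trend_raw: tuple
    trend_anon: tuple

    def to_dict(self) -> dict:
        return {
            "kind": "anon-scatter",
            "method": self.method,
            "params": dict(self.params),
            "x": self.x.tolist(),
            "y": self.y.tolist(),
            "multiplicity": self.multiplicity.tolist(),
            "trend_raw": list(self.trend_raw),
            "trend_anon": list(self.trend_anon),
        }


def scatter_anon_payload(
    cloud: PointCloud,
    method: str,
    *,
    k: int = 3,
    q: float = 0.25,
    metric: str = "euclidean-zscore",
    secret: SecretSeed | None = None,
) -> AnonScatterPayload:
    """Anonymize a point cloud with the det or prob engine and package it for plotting."""
    if method == "det":
        anon = deterministic_anonymize(cloud, k, metric)
        x, y = anon.x, anon.y
        mult = anon.multiplicity
        params = {"k": k, "metric": metric}
    elif method == "prob":
        if secret is None:
            raise ValidationError("probabilistic method requires a SecretSeed")
        noisy = probabilistic_anonymize(cloud, q, secret)
        x, y = noisy.x, noisy.y
        mult = np.ones(len(x), dtype=np.int64)
        params = {"q": q}
    else:
        raise ValidationError(f"method must be 'det' or 'prob', got {method!r}")
    return AnonScatterPayload(
        x,
        y,
        method,
        params,
        mult,
        trend_raw=trend_line(cloud.x, cloud.y),
        trend_anon=trend_line(x, y),
    )


# ---------------------------------------------------------------------------
# heat map / contour
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurfacePayload:
    """A density grid destined for a heat map or contour rendering.

    Heat maps and contours built from the same source share the identical
    grid; only the rendering hint differs.  Suppressed cells carry no value.
    """

    grid: DensityGrid
    kind: str  # "heatmap" | "contour"
    method: str
    params: dict

    def to_dict(self) -> dict:
        mask = self.grid.suppressed
        counts = [
            _masked_list(row, mrow) for row, mrow in zip(self.grid.counts, mask)
        ]
        return {
            "kind": self.kind,
            "method": self.method,
            "params": dict(self.params),
            "x_edges": self.grid.x_spec.edges.tolist(),
            "y_edges": self.grid.y_spec.edges.tolist(),
            "counts": counts,
            "mask": mask.tolist(),
        }


def surface_payload(
    source,
    gx: int = 30,
    gy: int = 30,
    threshold: int = 3,
    generalize_factor: int = 1,
    kind: str = "heatmap",
) -> SurfacePayload:
    """Build a heat-map/contour grid payload from raw or anonymized points.

    A raw :class:`PointCloud` follows the k-anonymization path (optional
    generalization, then suppression at *threshold*); a
    :class:`CentroidCloud` or :class:`NoisyCloud` is gridded with no further
    suppression, as its points are already anonymized.
    """
    if kind not in ("heatmap", "contour"):
        raise ValidationError("kind must be 'heatmap' or 'contour'")
    if isinstance(source, PointCloud):
        grid = grid_density(source, gx, gy)
        if generalize_factor > 1:
            grid = generalize(grid, generalize_factor)
        grid = suppress(grid, threshold)
        method = "kanon"
        params = {"threshold": threshold, "generalize_factor": generalize_factor}
    elif isinstance(source, CentroidCloud):
        grid = grid_density(PointCloud(source.x, source.y), gx, gy)
        method = "det"
        params = {"k": source.k, "metric": source.metric}
    elif isinstance(source, NoisyCloud):
        grid = grid_density(PointCloud(source.x, source.y), gx, gy)
        method = "prob"
        params = {"q": source.q}
    else:
        raise ValidationError(f"unsupported source type {type(source).__name__}")
    return SurfacePayload(grid, kind, method, params)


# ---------------------------------------------------------------------------
# box plot
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoxplotStats:
    """Five-number summary plus outliers for one variable.

    Quartiles use linear interpolation between order statistics; whiskers
    reach the most extreme data points within 1.5 * IQR of the quartiles
    (``whisker_mode="minmax"`` instead puts them at the data extremes).
    """

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray
    n: int
    method: str
    params: dict

    def to_dict(self) -> dict:
        return {
            "kind": "boxplot",
            "method": self.method,
            "params": dict(self.params),
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "whisker_low": self.whisker_low,
            "whisker_high": self.whisker_high,
            "outliers": np.asarray(self.outliers).tolist(),
            "n": self.n,
        }


def _box_stats(values, method: str, params: dict, whisker_mode: str) -> BoxplotStats:
    v = np.asarray(values, dtype=np.float64)
    if len(v) < 5:
        warnings.warn(
            f"only {len(v)} values survive: box plot statistics are unreliable",
            stacklevel=3,
        )
    if len(v) == 0:
        raise ValidationError("no values left to summarize")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    if whisker_mode == "minmax":
        lo, hi = float(v.min()), float(v.max())
        out = np.array([])
    elif whisker_mode == "iqr":
        iqr = q3 - q1
        fence_lo, fence_hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= fence_lo) & (v <= fence_hi)]
        lo, hi = float(inside.min()), float(inside.max())
        out = np.sort(v[(v < lo) | (v > hi)])
    else:
        raise ValidationError("whisker_mode must be 'iqr' or 'minmax'")
    return BoxplotStats(float(med), float(q1), float(q3), lo, hi, out, len(v), method, params)


def boxplot_payload(
    data,
    method: str = "raw",
    *,
    gx: int = 30,
    gy: int = 30,
    threshold: int = 3,
    generalize_factor: int = 1,
    k: int = 3,
    q: float = 0.25,
    secret: SecretSeed | None = None,
    whisker_mode: str = "iqr",
):
    """Privacy-preserving box-plot statistics.

    For the k-anonymization path *data* must be a :class:`PointCloud`: the
    cloud is gridded, small cells are suppressed, and the statistics are
    computed on the raw values of the observations in surviving cells (one
    :class:`BoxplotStats` per variable).  The det/prob paths anonymize the
    values first and summarize those; a 1-D series gets a single summary.
    """
    if method in ("suppress", "generalize", "kanon"):
        if not isinstance(data, PointCloud):
            raise ValidationError("k-anonymization box plots need a PointCloud")
        grid = grid_density(data, gx, gy)
        factor = generalize_factor if method != "suppress" else 1
        if factor > 1:
            grid = generalize(grid, factor)
        grid = suppress(grid, threshold)
        cells = observation_cells(data, grid)
        keep = ~grid.suppressed[cells[:, 0], cells[:, 1]]
        params = {"threshold": threshold, "generalize_factor": factor}
        return (
            _box_stats(data.x[keep], method, params, whisker_mode),
            _box_stats(data.y[keep], method, params, whisker_mode),
        )
    if isinstance(data, PointCloud):
        if method == "raw":
            return (
                _box_stats(data.x, method, {}, whisker_mode),
                _box_stats(data.y, method, {}, whisker_mode),
            )
        if method == "det":
            anon = deterministic_anonymize(data, k)
            params = {"k": k}
            return (
                _box_stats(anon.x, method, params, whisker_mode),
                _box_stats(anon.y, method, params, whisker_mode),
            )
        if method == "prob":
            if secret is None:
                raise ValidationError("probabilistic method requires a SecretSeed")
            noisy = probabilistic_anonymize(data, q, secret)
            params = {"q": q}
            return (
                _box_stats(noisy.x, method, params, whisker_mode),
                _box_stats(noisy.y, method, params, whisker_mode),
            )
        raise ValidationError(f"unknown method {method!r}")
    values = np.asarray(data, dtype=np.float64)
    if method == "raw":
        return _box_stats(values, method, {}, whisker_mode)
    if method == "det":
        return _box_stats(deterministic_anonymize_series(values, k), method, {"k": k}, whisker_mode)
    if method == "prob":
        if secret is None:
            raise ValidationError("probabilistic method requires a SecretSeed")
        noisy = probabilistic_anonymize(values, q, secret)
        return _box_stats(noisy.values, method, {"q": q}, whisker_mode)
    raise ValidationError(f"unknown method {method!r}")
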