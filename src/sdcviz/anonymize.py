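"""The three disclosure-control engines.

* **k-anonymization by suppression/generalization** operates on binned data:
  a bin or grid cell whose non-zero count falls below a threshold k is masked
  (small cell counts rule); generalization merges adjacent bins/cells into
  coarser ones before the rule is applied.
* **Deterministic (kNN-centroid) anonymization** replaces every record by the
  centroid of the cluster formed by itself and its k-1 nearest neighbours,
  then rescales the centroids so each dimension recovers the original mean
  and standard deviation exactly.
* **Probabilistic (additive-noise) anonymization** adds zero-mean Gaussian
  noise with standard deviation q times the observed standard deviation of
  each variable.  Draws are a deterministic function of (secret key, data
  fingerprint, variable name), so the release is reproducible under the
  secret key while the key itself never appears in any output.

All engines operate on 1-D series or 2-D point clouds and are independent of
any particular plot.

Conventions (fixed package-wide):

* Bins/grid cells are left-closed right-open, except the last interval which
  is closed; edges are anchored at the observed min/max, so counts always sum
  to n.  This is numpy's histogram convention.
* Standard deviations use the n-1 (sample) denominator throughout.
* Exact kNN distance ties are broken by lowest record index, making the
  deterministic engine genuinely deterministic.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg

from . import synthgen
from .errors import (
    ConstantVariableError,
    DegenerateRangeError,
    DegenerateScalingError,
    ReanonymizationError,
    SingularCovarianceError,
    ValidationError,
)

METRICS = ("euclidean-zscore", "mahalanobis")

# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PointCloud:
    """An ordered set of n bivariate observations; the index identifies the record."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=np.float64)
        y = np.asarray(self.y, dtype=np.float64)
        if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
            raise ValidationError("x and y must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValidationError("coordinates must be finite")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.x)

    @classmethod
    def from_table(cls, table: pd.DataFrame, x: str = "X", y: str = "Y") -> "PointCloud":
        return cls(table[x].to_numpy(dtype=np.float64), table[y].to_numpy(dtype=np.float64))

    def to_table(self, x: str = "X", y: str = "Y") -> pd.DataFrame:
        return pd.DataFrame({x: self.x, y: self.y})


@dataclass(frozen=True)
class BinSpec:
    """Strictly increasing edges defining consecutive intervals.

    Intervals are left-closed right-open except the last, which is closed.
    """

    edges: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=np.float64)
        if edges.ndim != 1 or len(edges) < 2:
            raise ValidationError("BinSpec needs at least 2 edges")
        if not np.all(np.diff(edges) > 0):
            raise ValidationError("edges must be strictly increasing")
        object.__setattr__(self, "edges", edges)

    @property
    def nbins(self) -> int:
        return len(self.edges) - 1

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass(frozen=True)
class BinnedSeries:
    """Per-bin counts of a single variable plus a suppression mask."""

    spec: BinSpec
    counts: np.ndarray
    suppressed: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if len(counts) != self.spec.nbins:
            raise ValidationError("counts length must equal number of bins")
        if np.any(counts < 0):
            raise ValidationError("counts must be non-negative")
        mask = self.suppressed
        mask = np.zeros(len(counts), bool) if mask is None else np.asarray(mask, bool)
        if len(mask) != len(counts):
            raise ValidationError("mask length must equal number of bins")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "suppressed", mask)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class DensityGrid:
    """2-D count matrix over rectangular cells, with a suppression mask.

    ``counts[i, j]`` is the number of observations in x-bin i and y-bin j.
    """

    x_spec: BinSpec
    y_spec: BinSpec
    counts: np.ndarray
    suppressed: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (self.x_spec.nbins, self.y_spec.nbins):
            raise ValidationError("counts shape must be (x bins, y bins)")
        if np.any(counts < 0):
            raise ValidationError("counts must be non-negative")
        mask = self.suppressed
        mask = np.zeros(counts.shape, bool) if mask is None else np.asarray(mask, bool)
        if mask.shape != counts.shape:
            raise ValidationError("mask shape must match counts")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "suppressed", mask)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class CentroidCloud:
    """Deterministically anonymized points with cluster size, metric and multiplicities.

    ``multiplicity[i]`` is the number of output points coincident with point i
    (including itself); values > 1 mark the positions the paper-style plots
    flag with black dots.
    """

    x: np.ndarray
    y: np.ndarray
    k: int
    metric: str
    multiplicity: np.ndarray

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class NoisySeries:
    """A noise-anonymized 1-D series."""

    values: np.ndarray
    q: float
    noise_sd: float

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class NoisyCloud:
    """A noise-anonymized point cloud; ``noise_sd`` is per-dimension (x, y)."""

    x: np.ndarray
    y: np.ndarray
    q: float
    noise_sd: tuple

    def __len__(self) -> int:
        return len(self.x)


class SecretSeed:
    """Confidential key binding noise draws to the data they protect.

    The per-variable random stream is seeded with a hash of
    ``(key, data fingerprint, variable name)``: the same key on the same data
    always reproduces the same noise (so repeated releases leak nothing new),
    while the key itself is never serialized, logged or repr'd.
    """

    __slots__ = ("_key",)

    def __init__(self, key) -> None:
        self._key = str(key)

    def rng(self, data_fingerprint: str, variable: str) -> np.random.Generator:
        material = f"{self._key}|{data_fingerprint}|{variable}".encode()
        digest = hashlib.sha256(material).digest()
        seed = int.from_bytes(digest[:8], "big")
        return np.random.default_rng(seed)

    def key_digest(self) -> str:
        """Non-reversible identifier of the key (safe to keep in a registry)."""
        return hashlib.sha256(self._key.encode()).hexdigest()

    def __repr__(self) -> str:  # never reveal the key
        return "SecretSeed(<redacted>)"

    __str__ = __repr__


# ---------------------------------------------------------------------------
# binning, suppression, generalization
# ---------------------------------------------------------------------------


def _edges_from_width(lo: float, hi: float, width: float) -> np.ndarray:
    if width <= 0:
        raise ValidationError("width must be positive")
    span = hi - lo
    nb = max(1, math.ceil(span / width - 1e-12))
    return lo + width * np.arange(nb + 1)


def bin_series(values, *, width: float | None = None, nbins: int | None = None) -> BinnedSeries:
    """Bin a 1-D series into equal-width intervals spanning its observed range.

    Exactly one of *width* or *nbins* must be given.  With *width*, edges start
    at the observed minimum and extend in steps of *width* until the maximum is
    covered (the last bin may overhang).  With *nbins*, the range is split into
    that many equal intervals.  Counts always sum to n.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 1 or len(v) == 0:
        raise ValidationError("values must be a non-empty 1-D array")
    if (width is None) == (nbins is None):
        raise ValidationError("give exactly one of width or nbins")
    lo, hi = float(v.min()), float(v.max())
    if width is not None:
        edges = _edges_from_width(lo, hi, float(width))
    else:
        if nbins < 1:
            raise ValidationError("nbins must be >= 1")
        if hi == lo:
            if nbins > 1:
                raise DegenerateRangeError(
                    "all values identical: cannot form more than one equal-width bin"
                )
            edges = np.array([lo - 0.5, lo + 0.5])
        else:
            edges = np.linspace(lo, hi, nbins + 1)
    counts, _ = np.histogram(v, bins=edges)
    return BinnedSeries(BinSpec(edges), counts)


def suppress(binned, threshold: int):
    """Apply the small cell counts rule: mask cells with 0 < count < threshold.

    Zero-count cells are empty, not "suppressed"; cells at or above the
    threshold are never masked.  Works on a :class:`BinnedSeries` or a
    :class:`DensityGrid`; returns the same type with the mask OR-ed in.
    """
    if threshold < 1:
        raise ValidationError("threshold must be >= 1")
    mask = (binned.counts > 0) & (binned.counts < threshold)
    return replace(binned, suppressed=binned.suppressed | mask)


def _group_boundaries(nbins: int, m: int) -> np.ndarray:
    # groups of m adjacent bins; the last group absorbs any remainder
    nfull = nbins // m
    if nfull == 0:
        return np.array([0, nbins])
    bounds = list(range(0, nfull * m, m))
    return np.array(bounds + [nbins])


def generalize(binned, factor: int):
    """Coarsen bins by merging groups of *factor* adjacent bins.

    Merged counts are sums of their members (totals conserved); if *factor*
    does not divide the bin count, the last merged group absorbs the
    remainder.  The suppression mask is reset — re-apply :func:`suppress`
    after generalizing, as suppression decisions belong to the coarse grid.
    """
    if factor < 1:
        raise ValidationError("generalization factor must be >= 1")
    if factor == 1:
        return replace(binned)
    if isinstance(binned, BinnedSeries):
        b = _group_boundaries(binned.spec.nbins, factor)
        counts = np.add.reduceat(binned.counts, b[:-1])
        edges = binned.spec.edges[b]
        return BinnedSeries(BinSpec(edges), counts)
    if isinstance(binned, DensityGrid):
        bx = _group_boundaries(binned.x_spec.nbins, factor)
        by = _group_boundaries(binned.y_spec.nbins, factor)
        counts = np.add.reduceat(np.add.reduceat(binned.counts, bx[:-1], axis=0), by[:-1], axis=1)
        return DensityGrid(
            BinSpec(binned.x_spec.edges[bx]), BinSpec(binned.y_spec.edges[by]), counts
        )
    raise ValidationError(f"cannot generalize object of type {type(binned).__name__}")


def grid_density(cloud: PointCloud, gx: int, gy: int) -> DensityGrid:
    """Count observations on a gx-by-gy equal-width grid over the observed ranges."""
    if gx < 1 or gy < 1:
        raise ValidationError("grid dimensions must be >= 1")
    if len(cloud) < 1:
        raise ValidationError("cloud must be non-empty")
    for v, name in ((cloud.x, "x"), (cloud.y, "y")):
        if v.min() == v.max():
            raise DegenerateRangeError(f"{name} has zero range: grid is degenerate")
    ex = np.linspace(cloud.x.min(), cloud.x.max(), gx + 1)
    ey = np.linspace(cloud.y.min(), cloud.y.max(), gy + 1)
    counts, _, _ = np.histogram2d(cloud.x, cloud.y, bins=[ex, ey])
    return DensityGrid(BinSpec(ex), BinSpec(ey), counts.astype(np.int64))


def observation_cells(cloud: PointCloud, grid: DensityGrid) -> np.ndarray:
    """Map each observation to its (x bin, y bin) cell indices on *grid*.

    Uses the same closure convention as the counting (last bin closed), so
    the implied per-cell tallies match ``grid.counts`` for points inside the
    grid's span.  Points outside the span get index -1 in that dimension.
    """

    def _digitize(v: np.ndarray, edges: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(edges, v, side="right") - 1
        idx[v == edges[-1]] = len(edges) - 2  # last bin is closed
        idx[(v < edges[0]) | (v > edges[-1])] = -1
        return idx

    ix = _digitize(cloud.x, grid.x_spec.edges)
    iy = _digitize(cloud.y, grid.y_spec.edges)
    return np.column_stack([ix, iy])


# ---------------------------------------------------------------------------
# standardization and distances
# ---------------------------------------------------------------------------


def zscore(values):
    """Standardize to mean 0 and sample sd 1; returns ``(z, mu, sigma)`` for inversion."""
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 1 or len(v) < 2:
        raise ValidationError("need at least 2 values to standardize")
    mu = float(v.mean())
    sigma = float(v.std(ddof=1))
    if sigma == 0.0:
        raise ConstantVariableError("variable is constant: sd is zero")
    return (v - mu) / sigma, mu, sigma


def mahalanobis(u, v, cov) -> float:
    """Covariance-adjusted distance sqrt((u-v)^T Sigma^-1 (u-v)).

    Reduces to normalized Euclidean for diagonal Sigma and to plain Euclidean
    for the identity.  Sigma must be symmetric positive definite.
    """
    d = np.asarray(u, dtype=np.float64) - np.asarray(v, dtype=np.float64)
    cov = np.asarray(cov, dtype=np.float64)
    if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
        raise SingularCovarianceError("covariance must be a symmetric 2x2 matrix")
    try:
        L = scipy.linalg.cholesky(cov, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise SingularCovarianceError("covariance is not positive definite") from exc
    w = scipy.linalg.solve_triangular(L, d, lower=True)
    return float(np.sqrt(w @ w))


def _whiten(points: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Transform points so Euclidean distance equals Mahalanobis under *cov*."""
    try:
        L = scipy.linalg.cholesky(cov, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise SingularCovarianceError("covariance is not positive definite") from exc
    return scipy.linalg.solve_triangular(L, points.T, lower=True).T


# ---------------------------------------------------------------------------
# deterministic (kNN-centroid) anonymization
# ---------------------------------------------------------------------------


def _knn_clusters(coords: np.ndarray, k: int) -> np.ndarray:
    """Cluster membership: row i lists the k member indices of record i's cluster.

    The cluster is the record itself plus its k-1 nearest neighbours under
    Euclidean distance on *coords*; exact ties are broken by lowest index.
    """
    n = len(coords)
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    # stable sort on distances preserves index order among ties
    order = np.argsort(d2, axis=1, kind="stable")
    members = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        row = order[i]
        members[i, 0] = i
        members[i, 1:] = row[row != i][: k - 1]
    return members


def _rescale(values: np.ndarray, target_mean: float, target_sd: float) -> np.ndarray:
    """Center values on their own mean, stretch to target sd, shift to target mean."""
    m = values.mean()
    s = values.std(ddof=1) if len(values) > 1 else 0.0
    if s == 0.0:
        raise DegenerateScalingError(
            "all centroids coincide: variance-restoring rescale is undefined"
        )
    return (values - m) * (target_sd / s) + target_mean


def _multiplicity(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    pts = np.column_stack([x, y])
    _, inverse, counts = np.unique(pts, axis=0, return_inverse=True, return_counts=True)
    return counts[inverse]


def deterministic_anonymize(
    cloud: PointCloud, k: int, metric: str = "euclidean-zscore"
) -> CentroidCloud:
    """Replace each point by the rescaled centroid of itself and its k-1 nearest neighbours.

    With the default metric, neighbours are found by Euclidean distance on
    z-scored coordinates; with ``"mahalanobis"`` the raw coordinates are used
    under the covariance-adjusted metric (equivalent for standardized,
    uncorrelated data).  After averaging, centroids are rescaled per dimension
    so the output mean and sample sd equal the input's exactly.

    Records sharing an isolated cluster of size k get identical centroids;
    their multiplicity is recorded for coincidence marking.
    """
    n = len(cloud)
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, n]; got k={k}, n={n}")
    if metric not in METRICS:
        raise ValidationError(f"metric must be one of {METRICS}")
    if k < 3 or k > n - 3:
        warnings.warn(
            "recommended range for k is 3 <= k <= n-3 for adequate protection",
            stacklevel=2,
        )
    raw = np.column_stack([cloud.x, cloud.y])
    if metric == "euclidean-zscore":
        zx, _, _ = zscore(cloud.x)
        zy, _, _ = zscore(cloud.y)
        coords = np.column_stack([zx, zy])
    else:
        coords = _whiten(raw, np.cov(raw, rowvar=False, ddof=1))
    members = _knn_clusters(coords, k)
    cx = cloud.x[members].mean(axis=1)
    cy = cloud.y[members].mean(axis=1)
    if n >= 2:
        cx = _rescale(cx, cloud.x.mean(), cloud.x.std(ddof=1))
        cy = _rescale(cy, cloud.y.mean(), cloud.y.std(ddof=1))
    return CentroidCloud(cx, cy, k=k, metric=metric, multiplicity=_multiplicity(cx, cy))


def deterministic_anonymize_series(values, k: int) -> np.ndarray:
    """1-D kNN-centroid anonymization of a single variable.

    Same procedure as the bivariate engine applied to one attribute at a time
    (used for histograms, box plots and the pre-plot QQ variant): cluster each
    value with its k-1 nearest values (ties by lowest index), average, and
    rescale to the original mean and sd.
    """
    v = np.asarray(values, dtype=np.float64)
    n = len(v)
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, n]; got k={k}, n={n}")
    z, _, _ = zscore(v)
    members = _knn_clusters(z[:, None], k)
    c = v[members].mean(axis=1)
    return _rescale(c, v.mean(), v.std(ddof=1))


# ---------------------------------------------------------------------------
# probabilistic (additive-noise) anonymization
# ---------------------------------------------------------------------------

# fingerprint -> digest of the secret key it was first released under
_noise_registry: dict = {}


def reset_noise_registry() -> None:
    """Forget which secret keys have been used (e.g. between independent studies)."""
    _noise_registry.clear()


def _check_registry(fp: str, secret: SecretSeed, allow_rekey: bool) -> None:
    digest = secret.key_digest()
    seen = _noise_registry.get(fp)
    if seen is not None and seen != digest and not allow_rekey:
        raise ReanonymizationError(
            "this data fingerprint was already noise-anonymized under a different "
            "secret key; averaging releases under many keys recovers the raw values. "
            "Pass allow_rekey=True only if you understand this risk."
        )
    _noise_registry[fp] = digest


def _noisy_series(v: np.ndarray, q: float, rng: np.random.Generator):
    sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
    noise_sd = q * sd
    return v + rng.normal(0.0, noise_sd, len(v)), noise_sd


def probabilistic_anonymize(
    data, q: float, secret: SecretSeed, *, allow_rekey: bool = False
):
    """Add Gaussian noise with sd equal to a fraction *q* of each variable's observed sd.

    *data* is a :class:`PointCloud` (noise independent across dimensions and
    records) or a 1-D series.  Draws are reproducible under (*secret*, data),
    and by default the engine refuses to noise the same data under a second
    key: with fresh noise every release, averaging releases converges to the
    raw values.
    """
    if q < 0:
        raise ValidationError("q must be non-negative")
    if not isinstance(secret, SecretSeed):
        raise ValidationError("secret must be a SecretSeed")
    if isinstance(data, PointCloud):
        fp = synthgen.fingerprint(data.to_table())
        _check_registry(fp, secret, allow_rekey)
        nx, sdx = _noisy_series(data.x, q, secret.rng(fp, "X"))
        ny, sdy = _noisy_series(data.y, q, secret.rng(fp, "Y"))
        return NoisyCloud(nx, ny, q=q, noise_sd=(sdx, sdy))
    v = np.asarray(data, dtype=np.float64)
    if v.ndim != 1:
        raise ValidationError("data must be a PointCloud or 1-D series")
    fp = synthgen.fingerprint(pd.DataFrame({"value": v}))
    _check_registry(fp, secret, allow_rekey)
    nv, sd = _noisy_series(v, q, secret.rng(fp, "value"))
    return NoisySeries(nv, q=q, noise_sd=sd)
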