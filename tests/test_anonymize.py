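"""The three disclosure-control engines, checked against enumeration and oracles."""

import contextlib

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdcviz import (
    DatasetSpec,
    PointCloud,
    SecretSeed,
    bin_series,
    deterministic_anonymize,
    deterministic_anonymize_series,
    generate,
    generalize,
    grid_density,
    mahalanobis,
    probabilistic_anonymize,
    suppress,
    zscore,
)
from sdcviz.errors import (
    ConstantVariableError,
    DegenerateRangeError,
    DegenerateScalingError,
    ReanonymizationError,
    SingularCovarianceError,
    ValidationError,
)

from conftest import random_cloud

# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


def test_bin_series_symmetric_split():
    b = bin_series(np.arange(10.0), nbins=2)
    assert b.counts.tolist() == [5, 5]


def test_bin_series_boundary_goes_right_last_bin_closed():
    # under the left-closed convention 0.5 opens bin 2; 1.0 lands in the
    # closed last bin
    b = bin_series(np.array([0.0, 0.5, 1.0]), nbins=2)
    assert b.counts.tolist() == [1, 2]


def test_bin_series_fixed_width():
    x = generate(DatasetSpec("D1", 500, 3))["X"].to_numpy()
    b = bin_series(x, width=0.2)
    assert np.allclose(b.spec.widths, 0.2)
    assert b.counts.sum() == 500
    assert b.spec.edges[0] == x.min() and b.spec.edges[-1] >= x.max()


def test_bin_series_degenerate_range():
    with pytest.raises(DegenerateRangeError):
        bin_series(np.ones(5), nbins=3)


@given(st.lists(st.floats(-100, 100), min_size=1, max_size=200), st.integers(1, 20))
@settings(max_examples=60, derandomize=True, deadline=None)
def test_bin_counts_always_sum_to_n(values, nbins):
    v = np.asarray(values)
    if v.min() == v.max() and nbins > 1:
        return
    assert bin_series(v, nbins=nbins).counts.sum() == len(v)


# ---------------------------------------------------------------------------
# suppression / generalization
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "counts,k,expected",
    [
        ([5, 2, 7], 3, [False, True, False]),
        ([5, 2, 7], 1, [False, False, False]),
        ([0, 1, 2, 3], 3, [False, True, True, False]),
    ],
)
def test_suppression_mask_rule(counts, k, expected):
    """Mask exactly the cells with 0 < count < k; empty cells stay untouched."""
    b = bin_series(np.arange(float(len(counts))), nbins=len(counts))
    b = type(b)(b.spec, np.array(counts), None)
    assert suppress(b, k).suppressed.tolist() == expected


@given(st.lists(st.integers(0, 50), min_size=1, max_size=60), st.integers(1, 10))
@settings(max_examples=60, derandomize=True, deadline=None)
def test_suppression_never_masks_large_or_empty_cells(counts, k):
    from sdcviz import BinnedSeries, BinSpec

    b = BinnedSeries(BinSpec(np.arange(len(counts) + 1.0)), np.array(counts))
    mask = suppress(b, k).suppressed
    c = np.array(counts)
    assert not mask[c >= k].any()
    assert not mask[c == 0].any()
    assert mask[(c > 0) & (c < k)].all()


def test_generalize_pairwise_sums_and_identity():
    from sdcviz import BinnedSeries, BinSpec

    b = BinnedSeries(BinSpec(np.arange(5.0)), np.array([1, 2, 3, 4]))
    g = generalize(b, 2)
    assert g.counts.tolist() == [3, 7]
    assert g.spec.edges.tolist() == [0.0, 2.0, 4.0]
    assert generalize(b, 1).counts.tolist() == b.counts.tolist()


def test_generalize_remainder_absorbed_by_last_group():
    from sdcviz import BinnedSeries, BinSpec

    b = BinnedSeries(BinSpec(np.arange(6.0)), np.array([1, 2, 3, 4, 5]))
    g = generalize(b, 2)
    assert g.counts.tolist() == [3, 12]


def test_generalize_grid_30_to_15(d1_cloud):
    g = grid_density(d1_cloud, 30, 30)
    h = generalize(g, 2)
    assert h.counts.shape == (15, 15)
    assert h.n == g.n == 500


@given(st.lists(st.integers(0, 20), min_size=2, max_size=50), st.integers(1, 8))
@settings(max_examples=60, derandomize=True, deadline=None)
def test_generalize_conserves_totals(counts, m):
    from sdcviz import BinnedSeries, BinSpec

    b = BinnedSeries(BinSpec(np.arange(len(counts) + 1.0)), np.array(counts))
    assert generalize(b, m).counts.sum() == sum(counts)


def test_generalize_invalid_factor():
    from sdcviz import BinnedSeries, BinSpec

    b = BinnedSeries(BinSpec(np.arange(3.0)), np.array([1, 1]))
    with pytest.raises(ValidationError):
        generalize(b, 0)


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------


def test_grid_corner_points_one_per_cell():
    cloud = PointCloud(np.array([0.0, 0.0, 1.0, 1.0]), np.array([0.0, 1.0, 0.0, 1.0]))
    g = grid_density(cloud, 2, 2)
    assert g.counts.tolist() == [[1, 1], [1, 1]]


def test_grid_total_is_n(d1_cloud):
    g = grid_density(d1_cloud, 30, 30)
    assert g.n == 500 and g.counts.shape == (30, 30)


def test_grid_degenerate_range_error():
    cloud = PointCloud(np.ones(5), np.ones(5))
    with pytest.raises(DegenerateRangeError):
        grid_density(cloud, 3, 3)


# ---------------------------------------------------------------------------
# standardization and distance
# ---------------------------------------------------------------------------


def test_zscore_simple_and_roundtrip():
    z, mu, sigma = zscore(np.array([1.0, 2.0, 3.0]))
    assert np.allclose(z, [-1, 0, 1]) and mu == 2.0 and sigma == 1.0
    v = np.array([3.1, -2.0, 7.7, 0.4])
    z, mu, sigma = zscore(v)
    assert np.allclose(z * sigma + mu, v, atol=1e-12)


def test_zscore_constant_rejected():
    with pytest.raises(ConstantVariableError):
        zscore(np.full(4, 2.5))


def test_mahalanobis_reduces_to_euclidean_under_identity(rng):
    for _ in range(20):
        u, v = rng.normal(size=2), rng.normal(size=2)
        assert mahalanobis(u, v, np.eye(2)) == pytest.approx(
            np.linalg.norm(u - v), abs=1e-12
        )


def test_mahalanobis_diagonal_is_normalized_euclidean(rng):
    cov = np.diag([4.0, 9.0])
    u, v = rng.normal(size=2), rng.normal(size=2)
    expected = np.sqrt(((u - v) ** 2 / np.array([4.0, 9.0])).sum())
    assert mahalanobis(u, v, cov) == pytest.approx(expected, abs=1e-12)


def test_mahalanobis_closed_form_and_coincidence():
    assert mahalanobis((1, 0), (0, 0), [[4, 0], [0, 1]]) == pytest.approx(0.5)
    assert mahalanobis((2, 3), (2, 3), np.eye(2)) == 0.0


def test_mahalanobis_singular_covariance():
    with pytest.raises(SingularCovarianceError):
        mahalanobis((1, 0), (0, 0), [[1, 1], [1, 1]])


# ---------------------------------------------------------------------------
# deterministic anonymization
# ---------------------------------------------------------------------------


def brute_force_knn_centroids(x, y, k):
    """Independent oracle: z-score, all-pairs distances, (distance, index) sort,
    average raw coordinates over self + k-1 nearest, rescale per dimension."""
    n = len(x)
    zx = (x - x.mean()) / x.std(ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    cx = np.empty(n)
    cy = np.empty(n)
    for i in range(n):
        dists = [
            ((zx[i] - zx[j]) ** 2 + (zy[i] - zy[j]) ** 2, j) for j in range(n) if j != i
        ]
        dists.sort()
        members = [i] + [j for _, j in dists[: k - 1]]
        cx[i] = np.mean([x[j] for j in members])
        cy[i] = np.mean([y[j] for j in members])

    def rescale(c, raw):
        return (c - c.mean()) * (raw.std(ddof=1) / c.std(ddof=1)) + raw.mean()

    return rescale(cx, x), rescale(cy, y)


@pytest.mark.parametrize("k", [1, 2, 3, 5])
@pytest.mark.parametrize("n", [8, 15, 30])
def test_centroids_match_brute_force_oracle(rng, n, k):
    cloud = random_cloud(rng, n)
    ctx = pytest.warns(UserWarning) if (k < 3 or k > n - 3) else contextlib.nullcontext()
    with ctx:
        out = deterministic_anonymize(cloud, k)
    ox, oy = brute_force_knn_centroids(cloud.x, cloud.y, k)
    np.testing.assert_array_equal(out.x, ox)
    np.testing.assert_array_equal(out.y, oy)


def test_k1_is_identity_limit(d1_cloud):
    with pytest.warns(UserWarning):
        out = deterministic_anonymize(d1_cloud, 1)
    sigma = d1_cloud.x.std(ddof=1)
    assert np.max(np.abs(out.x - d1_cloud.x)) < 1e-12 * sigma
    assert np.max(np.abs(out.y - d1_cloud.y)) < 1e-12 * d1_cloud.y.std(ddof=1)


def test_mean_and_sd_preserved_exactly(d1_cloud):
    out = deterministic_anonymize(d1_cloud, 3)
    for o, r in ((out.x, d1_cloud.x), (out.y, d1_cloud.y)):
        sigma = r.std(ddof=1)
        assert abs(o.mean() - r.mean()) < 1e-9 * sigma
        assert abs(o.std(ddof=1) - sigma) < 1e-9 * sigma


def test_separated_triplets_collapse_to_two_centroids():
    """Two isolated clusters of size k share neighbours, hence centroids."""
    x = np.array([0.0, 0.1, 0.2, 10.0, 10.1, 10.2])
    y = np.array([0.0, 0.1, 0.2, 10.0, 10.1, 10.2])
    out = deterministic_anonymize(PointCloud(x, y), 3)
    distinct = np.unique(np.column_stack([out.x, out.y]), axis=0)
    assert len(distinct) == 2
    assert np.all(out.multiplicity == 3)


def test_k_out_of_range_rejected(rng):
    cloud = random_cloud(rng, 10)
    with pytest.raises(ValidationError):
        deterministic_anonymize(cloud, 11)
    with pytest.raises(ValidationError):
        deterministic_anonymize(cloud, 0)


def test_all_identical_centroids_degenerate():
    # n == k: every cluster is the whole cloud, so all centroids coincide
    cloud = PointCloud(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 2.0]))
    with pytest.warns(UserWarning), pytest.raises(DegenerateScalingError):
        deterministic_anonymize(cloud, 3)


def test_mahalanobis_metric_equivalent_for_standardized_data(rng):
    """For uncorrelated unit-variance data the two metrics give the same clusters."""
    x = rng.normal(size=60)
    y = rng.normal(size=60)
    x = (x - x.mean()) / x.std(ddof=1)
    # remove the sample correlation so the covariance is exactly diagonal
    y = y - x * np.polyfit(x, y, 1)[0]
    y = (y - y.mean()) / y.std(ddof=1)
    cloud = PointCloud(x, y)
    a = deterministic_anonymize(cloud, 5)
    b = deterministic_anonymize(cloud, 5, metric="mahalanobis")
    np.testing.assert_allclose(a.x, b.x, atol=1e-8)
    np.testing.assert_allclose(a.y, b.y, atol=1e-8)


def test_series_engine_matches_sorted_neighbour_logic():
    v = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
    out = deterministic_anonymize_series(v, 3)
    assert len(np.unique(out)) == 2  # two isolated triplets collapse
    assert out.mean() == pytest.approx(v.mean())
    assert out.std(ddof=1) == pytest.approx(v.std(ddof=1))


# ---------------------------------------------------------------------------
# probabilistic anonymization
# ---------------------------------------------------------------------------


def test_q_zero_is_bitwise_identity(d1_cloud):
    out = probabilistic_anonymize(d1_cloud, 0.0, SecretSeed("s"))
    np.testing.assert_array_equal(out.x, d1_cloud.x)
    np.testing.assert_array_equal(out.y, d1_cloud.y)


def test_same_key_reproduces_noise_different_key_does_not(d1_cloud):
    a = probabilistic_anonymize(d1_cloud, 0.25, SecretSeed("alpha"))
    b = probabilistic_anonymize(d1_cloud, 0.25, SecretSeed("alpha"))
    np.testing.assert_array_equal(a.x, b.x)
    np.testing.assert_array_equal(a.y, b.y)
    c = probabilistic_anonymize(d1_cloud, 0.25, SecretSeed("beta"), allow_rekey=True)
    assert not np.array_equal(a.x, c.x)


def test_second_key_refused_without_override(d1_cloud):
    probabilistic_anonymize(d1_cloud, 0.25, SecretSeed("alpha"))
    with pytest.raises(ReanonymizationError):
        probabilistic_anonymize(d1_cloud, 0.25, SecretSeed("beta"))


def test_noise_sd_fraction_of_observed_sd():
    v = generate(DatasetSpec("D1", 200_000, 17))["X"].to_numpy()
    out = probabilistic_anonymize(v, 0.25, SecretSeed("s"))
    injected = out.values - v
    target = 0.25 * v.std(ddof=1)
    assert out.noise_sd == pytest.approx(target)
    assert injected.std(ddof=1) == pytest.approx(target, rel=0.02)
    # variance of the q=0.25 noise is 6.25% of the data variance
    assert (out.noise_sd**2) / v.var(ddof=1) == pytest.approx(0.0625)


def test_noise_independent_across_dimensions(d1_cloud):
    out = probabilistic_anonymize(d1_cloud, 0.25, SecretSeed("s"))
    ex, ey = out.x - d1_cloud.x, out.y - d1_cloud.y
    assert abs(np.corrcoef(ex, ey)[0, 1]) < 0.15
    assert not np.array_equal(ex, ey)


def test_secret_never_appears_in_repr():
    s = SecretSeed("hunter2")
    assert "hunter2" not in repr(s) and "hunter2" not in str(s)


def test_negative_q_rejected(d1_cloud):
    with pytest.raises(ValidationError):
        probabilistic_anonymize(d1_cloud, -0.1, SecretSeed("s"))
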