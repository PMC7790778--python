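# Methods

`sdcviz` implements three statistical-disclosure-control (SDC) engines for
producing privacy-preserving visualization payloads from individual-level
continuous data, together with synthetic benchmark data, plot builders, a
disclosure audit, and parameter-sweep experiments. This note records the
models, the conventions the package fixes where the field leaves them open,
and what the tests do and do not demonstrate.

## The three engines

### k-anonymization by suppression and generalization

Operates on binned representations only (histogram bins, 2-D density-grid
cells). The *small cell counts rule* masks every cell whose non-zero count is
strictly below a threshold k; empty cells are left alone (they disclose
nothing and are visually distinct from withheld cells). *Generalization*
merges groups of m adjacent bins (or m×m blocks of cells) before the rule is
applied, conserving totals; if m does not divide the bin count the last merged
group absorbs the remainder. Serialized payloads withhold masked counts
entirely — a mask bit plus `null` — so no downstream renderer can leak them.

Conventions fixed here:

- **Bin closure.** Intervals are left-closed right-open with the last interval
  closed, and edges anchored at the observed min/max. This is the only
  equal-width convention under which every observation lands in some bin and
  counts always sum to n; it is also numpy's histogram convention, which the
  implementation uses directly.
- **Strict inequality.** Suppress iff 0 < count < k. A count equal to the
  threshold is publishable.
- **Suppression semantics after generalization.** `generalize` resets the
  mask; suppression is re-decided on the coarse grid, since the rule is a
  property of the released resolution.

The audit module reports (it does not act on) the residual risks of this
family: 100%-cells in grid margins, and the single-suppressed-cell /
marginal-total interaction for which complementary suppression would be
needed. Automatic complementary-cell selection is out of scope; there is no
canonical algorithm, and payloads produced here carry no marginal totals by
default.

### Deterministic (kNN-centroid) anonymization

Each record is replaced by the centroid of a cluster consisting of itself and
its k−1 nearest neighbours; one cluster per record, so unlike classical
microaggregation the clusters overlap. Centroids shrink toward the center of
mass, so they are then rescaled per dimension: centered on their own mean,
multiplied by sd(raw)/sd(centroids), and shifted to the raw mean. The output
mean and sample standard deviation therefore equal the input's exactly (to
floating tolerance), which is what makes the method useful for exploratory
displays.

Conventions fixed here:

- **Metric.** Default is Euclidean distance on z-scored coordinates;
  Mahalanobis distance on the raw coordinates is offered as an alternative
  (equivalent when the variables are standardized and uncorrelated; the
  implementation whitens with a Cholesky factor and reduces to normalized
  Euclidean for diagonal covariance).
- **Tie-breaking.** Exact distance ties are resolved by lowest record index
  (stable sort). Without this the "deterministic" method would not be.
- **Cluster size bounds.** 1 ≤ k ≤ n is accepted; k outside [3, n−3] emits a
  warning, since k < 3 gives weak protection and k near n collapses all
  centroids (k = n raises a degenerate-scaling error: every cluster is the
  whole sample and the rescale is undefined). k = 1 is the identity limit.
- **1-D variant.** Univariate displays (histograms, box plots, the pre-plot
  QQ option) use the same algorithm on the single variable.
- **No clipping.** Rescaled centroids can escape a bounded support (e.g. fall
  outside [0, 1] for a beta variable). This is a feature of the method — it
  further obscures outliers — and is reported by the audit as a support-bound
  warning, never silently corrected.

Isolated clusters of exactly k points share neighbour sets and produce
coincident centroids; the payload records each point's multiplicity so
renderers can flag positions representing several records. As k grows these
exact coincidences become rarer (neighbour sets differentiate), so the
distinct-position count rises toward n while the centroids themselves
compress toward the center of mass.

### Probabilistic (additive-noise) anonymization

Each variable independently receives Gaussian noise with mean zero and
standard deviation q times the variable's observed (n−1) standard deviation;
at the default q = 0.25 the noise variance is 6.25% of the data variance.
q = 0 is the bit-exact identity.

Seed handling operationalizes two requirements with one mechanism: the noise
stream is seeded from a SHA-256 hash of (secret key, data fingerprint,
variable name). The same key on the same data always reproduces the same
release (re-running an analysis leaks nothing new), the key never appears in
any payload, log or `repr`, and the engine refuses — absent an explicit
override — to noise a fingerprint it has already released under a different
key, because the mean of m independently-noised releases converges to the raw
values as m grows.

A known statistical consequence, documented rather than corrected: noise on a
predictor attenuates a fitted slope by the classical errors-in-variables
factor 1/(1+q²) (≈ 0.94 at q = 0.25). The tests verify this factor; correcting
inference on noisy data via measurement-error models is out of scope.

## Synthetic benchmark data

Three bivariate cohorts of 500 hypothetical individuals by default, chosen to
span symmetric/skewed, unbounded/semi-bounded/bounded, unimodal/bimodal
marginals and none/linear/non-linear relationships:

| name | X | Y |
|------|---|---|
| D1 | Normal(10, 0.5²) | X + Normal(0, 1) |
| D2 | Lognormal(log-mean 0, log-sd 0.5) | log X + Uniform(0, 1) |
| D3 | Beta(5, 2) | Beta(0.5, 0.5), independent of X |

Generators are bit-reproducible for a fixed (name, n, seed) via numpy's
PCG64. Published figures built on another ecosystem's generator are
reproduced *in distribution*, not draw-for-draw; accordingly all replicated
reference quantities are checked as replicate means against the single
printed realizations, within the empirical replicate spread. These cohorts
deliberately lack features of real data — missingness, measurement error,
heavy contamination, categorical structure — so passing tests demonstrate
engine correctness and distributional behaviour, not robustness to messy
inputs.

## Plot payloads

- **Histogram** — ordinate is frequency density (count / bin width), so the
  area identity density × width = count holds exactly for unsuppressed bins.
  k-anon path: bin raw values, generalize/suppress. det/prob paths: anonymize
  values first, then bin normally.
- **Sized-dot scatter (k-anon)** — grid, optionally generalize, suppress;
  one dot per surviving cell at the cell center, sized by count. Trend lines:
  ordinary least squares on the raw cloud, and a weighted least-squares fit
  through surviving cell centers with counts as weights. The payload reports
  a `hidden_fraction` = (n − number of dots)/n, i.e. observations in
  suppressed cells plus the per-cell aggregation excess Σ(count−1); for the
  normal/linear benchmark at 30×30/threshold 3 this exceeds one half.
- **Anonymized scatter (det/prob)** — the anonymized point cloud with
  multiplicity flags and both raw and anonymized trend coefficients.
- **Heat map / contour** — the same density grid feeds both; only the
  rendering hint differs. Grids of det/prob-anonymized points are *not*
  additionally suppressed (the plotted units are already anonymized values);
  this is a policy choice, and the audit still flags small cells on such
  grids as warnings. Contour level placement is a rendering concern and is
  kept out of the payload.
- **Box plots** — quartiles by linear interpolation between order statistics
  (the convention of most statistical environments); whiskers at the most
  extreme data points within 1.5·IQR of the quartiles, with a min/max mode
  offered since raw-data box plots are sometimes drawn that way. The k-anon
  path computes statistics on the raw values of observations in surviving
  grid cells; det/prob paths summarize the anonymized values.

## Regression diagnostics

OLS with intercept; leverage from the closed form h_i = 1/n + (x_i−x̄)²/Sxx;
Cook's distance D_i = e_i²h_i/(p s²(1−h_i)²) with p = 2 and s² the residual
mean square on n−2 degrees of freedom (cross-checked against statsmodels'
influence measures in the tests). Standardized residuals are e_i/sd(e) — the
simple definition, not internal studentization. QQ plotting positions are
(i−3/8)/(n+1/4) for n ≤ 10 and (i−1/2)/n otherwise.

Anonymization is applied to the constructed plot coordinates, each 2-D cloud
independently — the protocol that works for *any* scatter-like display. Its
known cost: 2-D noise on QQ pairs scrambles the ordering, turning the
expected coherent line into a scatter. The opt-in `qq_mode="pre-plot-1d"`
perturbs the standardized residuals before sorting and recomputes the pairs,
restoring monotonicity at the price of being QQ-specific (and, at high q, of
the noise itself dominating and looking Gaussian). Cook's-distance reference
contours (conventionally at 0.5 and 1) are a rendering concern; the payload
carries the D_i values only.

## Experiments

The sweep runner varies the suppression threshold (3, 5, 7, 9), the kNN
cluster size (5, 10, 20, 50) and the noise fraction (0.1, 0.5, 1, √2) across
sample sizes 50–500 with replicated datasets, and a paired base/doubled
generalization mode compares 30×30 vs 15×15 grids and 0.2 vs 0.4 histogram
widths. Because the underlying comparisons in the field are visual, five
scalar utility metrics were defined to make each qualitative conclusion
assertable: suppressed observation fraction (monotone in the threshold per
realization), trend-slope deviation, whisker-span ratio (range shrinkage),
distinct-centroid count, and a normalized per-cell L1 distance between
displayed and raw density grids. Replicate seeds derive from (base seed, n,
replicate) via a SeedSequence, so every row is reproducible independent of
execution order; infeasible combinations (cluster size exceeding n) are
skipped with a logged warning.

## Numerical choices and problem sizes

- Sample standard deviations use the n−1 denominator everywhere.
- The kNN search materializes the full distance matrix (O(n²) memory) with a
  stable argsort; exact and deterministic, appropriate for the n ≤ a few
  thousand this package targets.
- Replicated acceptance quantities use 200 replicates at n = 500; the noise
  variance law is checked at n = 10⁶; moment-recovery and slope-recovery
  checks run at n = 10⁵ within 4 standard errors. These sizes give
  Monte-Carlo error well below the tolerances tested.
- Degenerate inputs fail loudly with typed errors: zero-range data cannot be
  binned into multiple equal-width cells, constant variables cannot be
  z-scored, singular covariances are rejected, a perfect fit has no
  standardized residuals, and k = n collapses all centroids.

## Known limitations

- Only bivariate continuous data; categorical attributes are explicitly out
  of scope (perturbing category codes produces meaningless values).
- Only additive noise; multiplicative perturbation is not implemented.
- No optimal k-anonymity search: the engines apply a given
  suppression/generalization recipe, they do not choose one.
- No leverage-targeted noise, no measurement-error-corrected inference on
  noisy data, no formal re-identification risk scoring.
- The rekey guard is per-process state: it protects an analysis session, not
  a multi-host deployment (a shared registry would be needed there).
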