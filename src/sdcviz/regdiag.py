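"""Simple linear regression and privacy-preserving plot diagnostics.

The model is ordinary least squares with intercept, Yhat = b0 + b1 X.  Three
diagnostic coordinate sets are produced:

* residuals e_i against fitted values Yhat_i (linearity, homoscedasticity);
* a normal QQ plot of standardized residuals r_i = e_i / sd(e) against
  theoretical N(0,1) quantiles at the usual plotting positions;
* standardized residuals against leverage h_i (the hat-matrix diagonal),
  with Cook's distance D_i = e_i^2 h_i / (p s^2 (1-h_i)^2), p = 2,
  s^2 = RSS/(n-2).

Standardized residuals deliberately divide by the plain sample sd of the
residuals (not the internally studentized form): that is the definition used
for the QQ and leverage displays this module feeds.

Anonymization is applied to the *constructed plot coordinates*: the model is
fitted on the real data and each diagnostic 2-D cloud is then protected
independently with any of the three engines, exactly as a scatter plot would
be.  For QQ plots an opt-in variant (``qq_mode="pre-plot-1d"``) instead
perturbs the standardized residuals before sorting, which keeps the plotted
curve monotone at the price of being QQ-specific.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats
import statsmodels.api as sm

from .anonymize import (
    PointCloud,
    SecretSeed,
    deterministic_anonymize,
    deterministic_anonymize_series,
    probabilistic_anonymize,
)
from .errors import (
    DegenerateDiagnosticsError,
    SingularFitError,
    ValidationError,
)
from .plotdata import SizedDotPayload, scatter_kanon_payload


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of y on x with intercept, plus the quantities diagnostics need."""

    beta0: float
    beta1: float
    x: np.ndarray
    y: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    resid_sd: float
    hat: np.ndarray

    @property
    def n(self) -> int:
        return len(self.x)


def fit_ols(cloud: PointCloud) -> RegressionFit:
    """Fit Yhat = b0 + b1 X by least squares.

    Requires n >= 3 and a non-constant predictor.  By construction the
    residuals sum to zero, the leverages lie in [1/n, 1] and sum to 2.
    """
    x, y = cloud.x, cloud.y
    if len(x) < 3:
        raise ValidationError("need at least 3 observations to fit and diagnose")
    if x.min() == x.max():
        raise SingularFitError("predictor is constant: design matrix is singular")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    beta0, beta1 = (float(b) for b in res.params)
    fitted = np.asarray(res.fittedvalues)
    residuals = np.asarray(res.resid)
    # leverage for the simple linear model: h_i = 1/n + (x_i - xbar)^2 / Sxx
    dx = x - x.mean()
    hat = 1.0 / len(x) + dx**2 / np.sum(dx**2)
    return RegressionFit(
        beta0=beta0,
        beta1=beta1,
        x=x,
        y=y,
        fitted=fitted,
        residuals=residuals,
        resid_sd=float(residuals.std(ddof=1)),
        hat=hat,
    )


def qq_positions(n: int) -> np.ndarray:
    """Plotting positions for n ordered values: (i-3/8)/(n+1/4) for n <= 10, else (i-1/2)/n."""
    i = np.arange(1, n + 1)
    if n <= 10:
        return (i - 3.0 / 8.0) / (n + 0.25)
    return (i - 0.5) / n


@dataclass(frozen=True)
class DiagnosticsPayload:
    """Coordinate sets for the three diagnostic plots, raw or anonymized.

    Each plot is a 2-D cloud: ``resid_vs_fitted`` (fitted, residual),
    ``qq`` (theoretical quantile, ordered standardized residual) and
    ``resid_vs_leverage`` (leverage, standardized residual).  After
    k-anonymization a plot is replaced by its sized-dot payload.
    """

    resid_vs_fitted: object
    qq: object
    resid_vs_leverage: object
    standardized: np.ndarray
    cooks: np.ndarray
    method: str
    params: dict

    def _plot_dict(self, obj) -> object:
        if isinstance(obj, SizedDotPayload):
            return obj.to_dict()
        return {"x": obj.x.tolist(), "y": obj.y.tolist()}

    def to_dict(self) -> dict:
        return {
            "kind": "regression-diagnostics",
            "method": self.method,
            "params": dict(self.params),
            "resid_vs_fitted": self._plot_dict(self.resid_vs_fitted),
            "qq": self._plot_dict(self.qq),
            "resid_vs_leverage": self._plot_dict(self.resid_vs_leverage),
            "cooks": self.cooks.tolist(),
        }


def diagnostics(fit: RegressionFit) -> DiagnosticsPayload:
    """Raw diagnostic coordinates for *fit* (no anonymization)."""
    # a perfect fit leaves only rounding noise in the residuals
    if fit.resid_sd <= 1e-12 * max(np.abs(fit.y).max(), 1e-300):
        raise DegenerateDiagnosticsError(
            "residuals are (numerically) zero: standardized residuals undefined"
        )
    r = fit.residuals / fit.resid_sd
    n = fit.n
    theo = scipy.stats.norm.ppf(qq_positions(n))
    s2 = np.sum(fit.residuals**2) / (n - 2)
    p = 2
    cooks = fit.residuals**2 * fit.hat / (p * s2 * (1.0 - fit.hat) ** 2)
    return DiagnosticsPayload(
        resid_vs_fitted=PointCloud(fit.fitted, fit.residuals),
        qq=PointCloud(theo, np.sort(r)),
        resid_vs_leverage=PointCloud(fit.hat, r),
        standardized=r,
        cooks=cooks,
        method="raw",
        params={},
    )


def _anon_cloud(cloud, method, k, q, metric, secret, label):
    if method == "det":
        anon = deterministic_anonymize(cloud, k, metric)
        return PointCloud(anon.x, anon.y)
    noisy = probabilistic_anonymize(cloud, q, secret)
    return PointCloud(noisy.x, noisy.y)


def anonymized_diagnostics(
    payload: DiagnosticsPayload,
    method: str,
    *,
    gx: int = 30,
    gy: int = 30,
    threshold: int = 3,
    generalize_factor: int = 1,
    k: int = 3,
    q: float = 0.25,
    metric: str = "euclidean-zscore",
    secret: SecretSeed | None = None,
    qq_mode: str = "post-plot-2d",
) -> DiagnosticsPayload:
    """Anonymize each diagnostic plot's coordinate cloud independently.

    ``kanon`` builds a sized-dot payload per plot (grid, suppress), exactly
    as for a scatter plot; ``det``/``prob`` anonymize each 2-D cloud.  With
    the default ``qq_mode="post-plot-2d"`` the QQ pairs are perturbed after
    construction (so the plot generally loses monotonicity under noise);
    ``"pre-plot-1d"`` perturbs the standardized residuals, re-sorts, and
    recomputes the pairs, yielding a coherent monotone curve.
    """
    if method not in ("kanon", "det", "prob"):
        raise ValidationError(f"method must be kanon, det or prob, got {method!r}")
    if qq_mode not in ("post-plot-2d", "pre-plot-1d"):
        raise ValidationError(f"unknown qq_mode {qq_mode!r}")
    if method == "prob" and secret is None:
        raise ValidationError("probabilistic method requires a SecretSeed")

    plots = {
        "resid_vs_fitted": payload.resid_vs_fitted,
        "qq": payload.qq,
        "resid_vs_leverage": payload.resid_vs_leverage,
    }
    out = {}
    if method == "kanon":
        params = {"threshold": threshold, "generalize_factor": generalize_factor}
        for name, cloud in plots.items():
            out[name] = scatter_kanon_payload(
                cloud, gx, gy, threshold, generalize_factor
            )
    else:
        params = {"k": k, "metric": metric} if method == "det" else {"q": q}
        for name, cloud in plots.items():
            if name == "qq" and qq_mode == "pre-plot-1d":
                if method == "det":
                    perturbed = deterministic_anonymize_series(payload.standardized, k)
                else:
                    perturbed = probabilistic_anonymize(
                        payload.standardized, q, secret
                    ).values
                n = len(perturbed)
                theo = scipy.stats.norm.ppf(qq_positions(n))
                out[name] = PointCloud(theo, np.sort(perturbed))
            else:
                out[name] = _anon_cloud(cloud, method, k, q, metric, secret, name)
    params["qq_mode"] = qq_mode
    return DiagnosticsPayload(
        resid_vs_fitted=out["resid_vs_fitted"],
        qq=out["qq"],
        resid_vs_leverage=out["resid_vs_leverage"],
        standardized=payload.standardized,
        cooks=payload.cooks,
        method=method,
        params=params,
    )
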