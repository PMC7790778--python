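"""Exception hierarchy shared across the package."""


class SdcvizError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SdcvizError):
    """An unknown dataset name, method, or option value."""


class ValidationError(SdcvizError):
    """Input data or parameters violate a precondition."""


class DegenerateRangeError(ValidationError):
    """A variable has zero range, so equal-width bins cannot be formed."""


class ConstantVariableError(ValidationError):
    """A variable has zero standard deviation and cannot be standardized."""


class SingularCovarianceError(ValidationError):
    """The covariance matrix is singular or not positive definite."""


class DegenerateScalingError(SdcvizError):
    """All kNN centroids coincide, so the variance-restoring rescale is undefined."""


class SingularFitError(ValidationError):
    """The regression design matrix is singular (constant predictor)."""


class DegenerateDiagnosticsError(SdcvizError):
    """Residual standard deviation is zero; standardized residuals are undefined."""


class ReanonymizationError(SdcvizError):
    """The same data fingerprint was noise-anonymized under a second secret key.

    Averaging independently-noised releases of the same data recovers the raw
    values by the law of large numbers, so a second key requires an explicit
    override.
    """


class SchemaError(SdcvizError):
    """A payload does not conform to the expected JSON schema."""
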