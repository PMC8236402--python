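"""Exception types shared across the package."""


class CrossLagMedError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CrossLagMedError):
    """A simulation or run configuration is invalid (names the offending parameters)."""


class SchemaError(CrossLagMedError):
    """An input table is missing required columns or has the wrong shape."""


class EstimationError(CrossLagMedError):
    """A model fit failed (rank deficiency, separation, non-convergence, tiny stratum)."""
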