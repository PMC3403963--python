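"""Exception hierarchy for the pipeline."""


class SepsisPgxError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(SepsisPgxError):
    """A transfer file does not match the published column dictionary."""


class IntegrityError(SepsisPgxError):
    """Duplicate identifiers or inconsistent set membership."""


class BlindingError(SepsisPgxError):
    """An operation attempted to see outcome/genotype data before lock."""


class ConfigurationError(SepsisPgxError):
    """Missing or inconsistent study configuration."""


class InfeasibleError(SepsisPgxError):
    """A calibration target cannot be attained."""


class SeparationError(SepsisPgxError):
    """Complete or quasi-complete separation in a logistic fit."""


class EstimationError(SepsisPgxError):
    """A model fit is impossible (e.g. no informative matched sets)."""


class DependencyError(SepsisPgxError):
    """A pipeline stage was invoked before its prerequisites."""


class DataError(SepsisPgxError):
    """Invalid data values (e.g. an undeclared allele)."""
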