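"""Exception hierarchy.

CLI exit-code mapping: ConfigError/SchemaError -> 2, DegenerateDataError
(and its subclasses) -> 3, anything else -> 1.
"""


class SelectMRError(Exception):
    """Base class for all package errors."""


class ConfigError(SelectMRError, ValueError):
    """Invalid simulation or analysis configuration."""


class SchemaError(SelectMRError, ValueError):
    """A file does not match the expected column schema."""


class DegenerateDataError(SelectMRError, RuntimeError):
    """Data became degenerate (empty survivor set, no usable records)."""


class DegenerateSelectionError(DegenerateDataError):
    """Survival selection removed every individual."""


class NoInstrumentsError(DegenerateDataError):
    """Instrument screening or harmonization left no usable instruments."""


class EmptyIntersectionError(DegenerateDataError):
    """Exposure and outcome tables share no SNPs."""


class NotEstimableError(DegenerateDataError):
    """An estimator's minimum instrument count is not met."""


class IncompleteAuditError(SelectMRError, ValueError):
    """A declared (exposure, outcome) pair has no MR result."""
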