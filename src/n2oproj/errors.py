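"""Exception hierarchy used across the package."""


class N2OProjError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(N2OProjError, ValueError):
    """A precondition on an argument was violated."""


class DomainMismatchError(N2OProjError):
    """Two inputs do not share the same grid domain or calendar."""


class SchemaError(N2OProjError):
    """A feature table does not match the expected column schema."""


class DataError(N2OProjError):
    """Input data are unusable (too few records, missing values, ...)."""


class EmptyTableError(DataError):
    """A generated table is empty (e.g. no fertilized cells)."""


class CalibrationError(N2OProjError):
    """Surface calibration failed to reach the target window."""


class IncompleteYearError(DataError):
    """Monthly coverage of a cell-year is incomplete."""


class ConfigError(N2OProjError):
    """Inconsistent run configuration (e.g. scenario/member pathway mismatch)."""


class UndefinedScalingError(N2OProjError):
    """A country has a nonzero trajectory but zero baseline fertilizer."""


class UndefinedBaselineError(N2OProjError):
    """Relative change requested against a zero baseline."""
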