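"""Exception hierarchy shared across the pipeline stages."""


class SSAEEGError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SSAEEGError):
    """Input file does not match the expected tabular dialect."""


class EmptyInputError(SSAEEGError):
    """An operation received no usable data (empty file, empty table, too-short recording)."""


class DimensionError(SSAEEGError):
    """Array shapes incompatible with the requested operation."""


class NumericError(SSAEEGError):
    """Non-finite values where finite ones are required."""


class DegenerateInputError(SSAEEGError):
    """Signal content is degenerate (all-zero power, no defined samples)."""


class MulticollinearityError(SSAEEGError):
    """Regression design matrix is rank deficient.

    ``columns`` names the offending explanatory variables.
    """

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(message or f"rank-deficient design; offending columns: {self.columns}")


class EmptyModelError(SSAEEGError):
    """Significance screening removed every explanatory variable."""


class SchemaError(SSAEEGError):
    """A table is missing columns required by the operation."""
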