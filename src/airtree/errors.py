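"""Exception hierarchy for airtree."""


class AirtreeError(Exception):
    """Base class for all airtree errors."""


class Not3DError(AirtreeError):
    """Raised when a volume read from disk is not a 3D mask."""


class NonBinaryError(AirtreeError):
    """Raised when a volume's values cannot be interpreted as 0/1."""


class GridMismatchError(AirtreeError):
    """Raised when two volumes expected to share a grid do not."""


class EmptyMaskError(AirtreeError):
    """Raised when an operation requires at least one foreground voxel."""


class NoCarinaError(AirtreeError):
    """Raised when the airway component never splits below the trachea."""


class InvalidLabelError(AirtreeError):
    """Raised when a label volume contains codes outside the valid set."""


class MissingColumnError(AirtreeError):
    """Raised when a cohort table lacks a required column."""


class PhantomGeometryError(AirtreeError):
    """Raised when a requested phantom does not fit inside its grid."""


class DegenerateDataError(AirtreeError):
    """Raised when data are too degenerate for the requested statistic."""


class StageError(AirtreeError):
    """Pipeline failure wrapper carrying the name of the failed stage."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
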