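"""Exception hierarchy shared across the de-identification pipeline.

Every refusal that should abort a pipeline stage (and translate into a
non-zero CLI exit) derives from :class:`DeidError`.
"""


class DeidError(Exception):
    """Base class for all errors raised by this package."""


class MalformedHeaderError(DeidError):
    """Header blob is too short or structurally broken."""


class UnrecognizedFormatError(DeidError):
    """Not a NIfTI-1 or Analyze 7.5 header under either byte order."""


class UnknownFieldError(DeidError):
    """Field name not present in the header layout."""


class ProtectedFieldError(DeidError):
    """Attempt to edit a geometry/codec field that cannot be edited."""


class OversizeValueError(DeidError):
    """String value longer than the target char field."""


class UnsupportedDatatypeError(DeidError):
    """Voxel datatype code outside the supported set."""


class MalformedFileError(DeidError):
    """Image file inconsistent with its header (offsets, sizes)."""


class TableError(DeidError):
    """Malformed demographic table (ragged rows, bad cells)."""


class DuplicateIdError(TableError):
    """Duplicate subject ID in the table's ID column."""


class AmbiguousMatchError(DeidError):
    """One image file is claimable by more than one subject ID."""


class MatchError(DeidError):
    """Other associative-match failures (duplicates without --multiple, ...)."""


class BackendUnavailableError(DeidError):
    """Requested skull-strip backend is not installed."""


class AttestationError(DeidError):
    """Packaging refused because the operator has not attested inspection."""


class LeakError(DeidError):
    """Identifier leak detected in the shareable output."""


class PipelineError(DeidError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
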