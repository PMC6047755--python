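"""Exception taxonomy.

All package errors derive from :class:`HicboxError` so the CLI can map
"data problem" to a single exit code. Usage errors (bad flags) are left to
click and never raised from library code.
"""


class HicboxError(Exception):
    """Base class for all hicbox errors."""


class InputError(HicboxError):
    """Malformed or inconsistent user input (names the offending record)."""


class ConfigError(HicboxError):
    """Invalid configuration (empty resolution list, feature off-chromosome, ...)."""


class UnsupportedFormat(HicboxError):
    """The byte source is not a container this package can read."""


class MalformedContainer(HicboxError):
    """The container's structure is damaged or truncated."""


class CorruptBlock(MalformedContainer):
    """A stored block failed to decompress or parse; carries the block identity."""

    def __init__(self, message, chr_pair=None, resolution=None, block_number=None):
        super().__init__(message)
        self.chr_pair = chr_pair
        self.resolution = resolution
        self.block_number = block_number


class NormNotAvailable(HicboxError):
    """Requested (normalization, chromosome, resolution) is not stored."""


class ResolutionNotAvailable(HicboxError):
    """Requested bin size is not stored; carries the stored list."""

    def __init__(self, requested, available):
        super().__init__(
            f"resolution {requested} not stored; available: {sorted(available, reverse=True)}"
        )
        self.requested = requested
        self.available = tuple(available)


class NotFound(HicboxError):
    """Local path does not exist."""


class RemoteError(HicboxError):
    """HTTP failure; carries the status code."""

    def __init__(self, message, status=None):
        super().__init__(message)
        self.status = status


class RangeError(HicboxError):
    """Requested byte span lies (partly) beyond the end of the source."""


class RecordError(InputError):
    """A single data row of a track/annotation file is invalid; carries line number."""

    def __init__(self, message, line_number=None):
        super().__init__(message)
        self.line_number = line_number


class FormatError(InputError):
    """A track file's structure (not a single row) is invalid."""


class SchemaError(HicboxError):
    """A session URL or document is missing or mangling a required key."""


class LocalSourceError(HicboxError):
    """A session referencing local files cannot be encoded as a shareable URL."""


class InternalError(HicboxError):
    """Invariant violation that indicates a bug or index corruption, not bad input."""
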