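"""Exception hierarchy.

Every user-facing failure derives from :class:`TrackViewError` so the CLI can
map any library error to a nonzero exit with a stage-tagged message.
"""


class TrackViewError(Exception):
    """Base class for all trackview errors."""


class LocusNotFoundError(TrackViewError):
    """A locus query matched neither a chromosome nor a named feature."""


class MalformedLocusError(TrackViewError):
    """Locus text parsed but violates coordinate constraints (start > end)."""


class CapabilityError(TrackViewError):
    """A required capability (sequence source, raster backend, ...) is absent."""


class IndexRequiredError(TrackViewError):
    """Region query on an alignment store without a coordinate index."""


class ParseError(TrackViewError):
    """Malformed content in a text format; carries line number or offset."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class SchemaError(TrackViewError):
    """A tabular file is missing a required column."""


class ContractError(TrackViewError):
    """An operation precondition was violated by the caller."""


class FormatError(TrackViewError):
    """A binary container is corrupt or truncated."""


class VersionError(TrackViewError):
    """A binary container has an unsupported version."""


class UnknownGenomeError(TrackViewError):
    """Session names a genome id absent from the registry."""


class IncompleteLinkError(TrackViewError):
    """Launch link specifies neither genome nor locus."""


class PairingError(TrackViewError):
    """Launch link name= and file= lists have different lengths."""
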