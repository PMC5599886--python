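"""Exception hierarchy.

Every error raised by the package derives from :class:`TrackProvError`, so
callers (and the CLI, which maps them onto exit codes) can catch one type.
"""


class TrackProvError(Exception):
    """Base class for all trackprov errors."""


class RegistryError(TrackProvError):
    """Problems loading or querying the build registry."""


class RegistryConflictError(RegistryError):
    """A build id or alias collides with one already registered."""


class UnknownBuildError(RegistryError, KeyError):
    """Lookup of a build id/alias that is not in the registry."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


class SizesParseError(RegistryError):
    """A chrom.sizes table line that is not ``<name>\\t<length>``."""

    def __init__(self, path: str, line_no: int, message: str) -> None:
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = path
        self.line_no = line_no


class TrackFormatError(TrackProvError):
    """The track format cannot be detected or is not supported."""


class MalformedFileError(TrackFormatError):
    """Too many malformed data lines for the configured strictness."""


class AnnotationConflictError(TrackProvError):
    """An existing build annotation names a different build."""


class EmptyTrackError(TrackProvError):
    """An operation that needs records received a track with none."""


class ConfigurationError(TrackProvError):
    """An out-of-range parameter or an empty candidate set."""


class ChainParseError(TrackProvError):
    """Chain file is syntactically malformed."""

    def __init__(self, path: str, line_no: int, message: str) -> None:
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = path
        self.line_no = line_no


class ChainIntegrityError(TrackProvError):
    """Chain block sums disagree with the header spans."""

    def __init__(self, chain_id: int, message: str) -> None:
        super().__init__(f"chain {chain_id}: {message}")
        self.chain_id = chain_id


class FixtureInfeasibleError(TrackProvError):
    """A synthetic fixture cannot satisfy its discriminative contract."""
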