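"""Exception hierarchy for facesym."""


class FaceSymError(Exception):
    """Base class for all facesym errors."""


class InputError(FaceSymError):
    """Invalid user input (names, labels, configuration values)."""


class FormatError(FaceSymError):
    """Unreadable or malformed file."""


class AlignmentError(FaceSymError):
    """Degenerate landmark configuration during rigid alignment."""


class CorrespondenceError(FaceSymError):
    """Dense correspondence failed (singular warp, bad projection)."""


class ModelError(FaceSymError):
    """Shape-model construction or use failed."""


class StatisticsError(FaceSymError):
    """A statistical routine received a degenerate sample."""


class DomainError(FaceSymError):
    """A quantity fell outside its mathematical domain."""


class ConfigError(FaceSymError):
    """Invalid simulation or protocol configuration."""
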