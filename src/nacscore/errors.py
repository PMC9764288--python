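"""Exception hierarchy shared across the package."""


class NacscoreError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(NacscoreError, ValueError):
    """Degenerate or non-finite geometric input (coincident points, NaN coordinates)."""


class SelectionError(NacscoreError, LookupError):
    """An atom-role matcher resolved to zero or more than one atom, or an unknown label."""


class TrajectoryParseError(NacscoreError, ValueError):
    """A structure file could not be parsed; the message carries the offending line."""


class StructureMismatchError(NacscoreError, ValueError):
    """Frames of one trajectory do not share the same (chain, resseq, name) atom keys."""


class ReconstructionError(NacscoreError, ValueError):
    """A requested (d, theta1, theta2) set admits no coordinate embedding."""


class ConfigurationError(NacscoreError, ValueError):
    """A user-supplied table or config is missing a required entry."""
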