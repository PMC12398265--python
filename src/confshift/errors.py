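"""Exception hierarchy shared across the package."""


class ConfshiftError(Exception):
    """Base class for all package-specific errors."""


class EmptyInputError(ConfshiftError):
    """Input contained no usable records (e.g. a PDB with no atoms)."""


class FormatError(ConfshiftError):
    """A file could not be parsed; the message names the offending record."""


class TopologyMismatchError(ConfshiftError):
    """Frames/selections do not share the expected atom count."""


class ConfigError(ConfshiftError):
    """Invalid configuration (unknown names, duplicate keys, bad ranges)."""


class InputError(ConfshiftError):
    """An operation received arguments outside its domain."""


class DegenerateGeometryError(ConfshiftError):
    """Geometry too degenerate for a well-defined answer (e.g. collinear
    points in a superposition, zero-variance coordinates in a KDE)."""
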