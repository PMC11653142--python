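"""Exception hierarchy shared across the package."""


class FlexRestrainError(Exception):
    """Base class for all package-specific errors."""


class MalformedInput(FlexRestrainError):
    """Input text could not be parsed (empty file, bad record, bad line)."""


class RangeError(FlexRestrainError):
    """A numeric value lies outside its admissible range (e.g. pLDDT not in [0, 100])."""


class LengthMismatch(FlexRestrainError):
    """Two sequences/profiles that must have equal length do not."""


class UnknownCode(FlexRestrainError):
    """A secondary-structure character outside the accepted 8-state alphabet."""


class MissingScore(FlexRestrainError):
    """A pLDDT score is required but absent."""


class MissingSS(FlexRestrainError):
    """A secondary-structure class is required but absent."""


class DegenerateInput(FlexRestrainError):
    """Geometry too degenerate for the requested operation (collinear/coincident points)."""


class TooFewFrames(FlexRestrainError):
    """A trajectory operation needs more frames than were provided."""


class ConstantProfile(FlexRestrainError):
    """A correlation was requested on a zero-variance profile."""


class SpecError(FlexRestrainError):
    """A synthetic-fixture specification is invalid."""


class DivergenceError(FlexRestrainError):
    """Sampler coordinates ran away from the initial structure."""
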