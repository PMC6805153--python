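"""Exception hierarchy for freqtag.

Every error raised on a violated precondition derives from
:class:`FreqTagError` so callers can catch pipeline failures uniformly.
"""


class FreqTagError(Exception):
    """Base class for all freqtag errors."""


class InvalidGeometryError(FreqTagError):
    """Sensor/source geometry cannot support the requested operation."""


GeometryError = InvalidGeometryError


class DegenerateChannelError(FreqTagError):
    """A channel has zero baseline variance and cannot be pre-whitened."""


class DegenerateSourceError(FreqTagError):
    """A source has an all-zero gain block."""


class DegenerateSpectrumError(FreqTagError):
    """Background bins have zero spread; z-scoring is undefined."""


class EmptyInputError(FreqTagError):
    """An operation that needs at least one trial/unit received none."""


class AlignmentError(FreqTagError):
    """A requested frequency does not align with a spectral bin center."""


class PairingError(FreqTagError):
    """Paired samples have mismatched lengths."""


class SamplingError(FreqTagError):
    """A requested band exceeds the Nyquist frequency."""


class UndefinedPeakError(FreqTagError):
    """Normalized peak is undefined (target and neighbor power both zero)."""


class InfeasibleError(FreqTagError):
    """The equality-constrained inverse problem has no solution."""


class SolverError(FreqTagError):
    """The SOCP solver failed to converge."""


class DesignError(FreqTagError):
    """An ANOVA design is incomplete or unbalanced."""


class ConfigError(FreqTagError):
    """A run configuration violates an invariant."""
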