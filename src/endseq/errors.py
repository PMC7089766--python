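"""Exception hierarchy for the endseq package."""


class EndseqError(Exception):
    """Base class for all endseq-specific errors."""


class ParseError(EndseqError):
    """A text input (BED, bedGraph, truth table, sample sheet) failed to parse."""


class ConfigurationError(EndseqError):
    """Invalid parameter, enum value, or incompatible object combination."""


class UndefinedSignalError(EndseqError):
    """A normalized signal is undefined (e.g. zero library size or zero denominator)."""


class NormalizationError(EndseqError):
    """Spike-in normalization cannot be computed (no spike signal, zero fraction)."""


class SizingError(EndseqError):
    """A chromosome is too short to host the requested sites at the required spacing."""


class SiteNearEdgeError(EndseqError):
    """A break summit lies too close to a chromosome end for flank-based analysis."""
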