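"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`MCGRError`
so callers (and the CLI) can distinguish data problems from programming
errors.
"""


class MCGRError(Exception):
    """Base class for all errors raised by mcgr."""


class AlphabetError(MCGRError, ValueError):
    """A sequence contains characters outside {A, C, G, T}."""


class ParameterError(MCGRError, ValueError):
    """A parameter is out of range or a size guard was exceeded."""


class BoundsError(MCGRError, ValueError):
    """A coordinate lies outside its 2^n x 2^n grid."""


class CodecError(MCGRError):
    """Base class for encoding/decoding failures."""


class FramingError(CodecError):
    """DNA length is not a multiple of the code word length."""


class DecodeError(CodecError):
    """A word in the DNA stream is not in the codebook."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        #: nucleotide offset of the offending word, if known
        self.offset = offset


class CorruptionError(CodecError):
    """A decoded index is outside the addressable range 0..2^b-1."""


class TruncationError(CodecError):
    """The declared payload length exceeds the bits actually present."""
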