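"""Lexicographic binary <-> DNA codec.

The codebook is sorted lexicographically (A<C<G<T); the bit stream is cut
into blocks of ``b = floor(log2 |C|)`` bits (MSB first, both within bytes
and within blocks) and each block value indexes a code word.  Only the
first ``2^b`` words are ever addressed.

Termination: a 64-bit big-endian payload-bit-length header is prepended
and carried through the same block mechanism, so the decoder knows exactly
how many payload bits to keep and discards the right-zero padding of the
final partial block.  ``with_header=False`` switches to the bare stream
(used for worked examples and rate experiments).
"""

from __future__ import annotations

import numpy as np

from .codebook import Codebook
from .errors import (
    CorruptionError,
    DecodeError,
    FramingError,
    ParameterError,
    TruncationError,
)

HEADER_BITS = 64


def block_size(codebook_size: int) -> int:
    """Bits carried per code word: ``floor(log2(size))`` by integer bit
    length -- never floating point.

    >>> block_size(484263)
    18
    """
    if codebook_size < 2:
        raise ParameterError(f"a codebook of size {codebook_size} cannot carry information")
    return codebook_size.bit_length() - 1


def _bits_to_blocks(bits: np.ndarray, b: int) -> np.ndarray:
    pad = (-len(bits)) % b
    if pad:
        bits = np.concatenate([bits, np.zeros(pad, dtype=np.uint8)])
    weights = (1 << np.arange(b - 1, -1, -1)).astype(np.int64)
    return bits.reshape(-1, b).astype(np.int64) @ weights


def encode(payload: bytes, book: Codebook, *, with_header: bool = True) -> str:
    """Encode a byte string as concatenated code words."""
    if len(book) < 2:
        raise ParameterError("codebook must contain at least 2 words")
    b = block_size(len(book))
    stream = payload
    if with_header:
        stream = (8 * len(payload)).to_bytes(HEADER_BITS // 8, "big") + payload
    bits = np.unpackbits(np.frombuffer(stream, dtype=np.uint8))
    if len(bits) == 0:
        return ""
    blocks = _bits_to_blocks(bits, b)
    words = np.array(book.words, dtype=f"<U{book.word_length}")
    return "".join(words[blocks])


def decode(dna: str, book: Codebook, *, with_header: bool = True) -> bytes:
    """Recover the byte string from concatenated code words.

    Raises :class:`FramingError` if the DNA length is not a multiple of the
    word length, :class:`DecodeError` (with nucleotide offset) for unknown
    words, :class:`CorruptionError` for indices the encoder can never emit,
    and :class:`TruncationError` if the declared payload length exceeds the
    available bits.
    """
    n = book.word_length
    if len(dna) % n:
        raise FramingError(f"DNA length {len(dna)} is not a multiple of the word length {n}")
    if not dna:
        if with_header:
            raise TruncationError("empty DNA stream cannot carry the length header")
        return b""
    b = block_size(len(book))
    index_of = {w: i for i, w in enumerate(book.words)}
    limit = 1 << b
    values = np.empty(len(dna) // n, dtype=np.int64)
    for j in range(len(values)):
        word = dna[j * n : (j + 1) * n]
        try:
            idx = index_of[word]
        except KeyError:
            raise DecodeError(
                f"word {word!r} at nucleotide offset {j * n} is not in the codebook",
                offset=j * n,
            ) from None
        if idx >= limit:
            raise CorruptionError(
                f"word {word!r} at nucleotide offset {j * n} has index {idx} >= 2^{b};"
                " the encoder never emits it"
            )
        values[j] = idx
    bits = ((values[:, None] >> np.arange(b - 1, -1, -1)) & 1).astype(np.uint8).ravel()
    if with_header:
        if len(bits) < HEADER_BITS:
            raise TruncationError("stream shorter than the 64-bit length header")
        payload_bits = int.from_bytes(np.packbits(bits[:HEADER_BITS]).tobytes(), "big")
        if payload_bits % 8:
            raise CorruptionError(f"declared payload length {payload_bits} is not a whole number of bytes")
        if payload_bits > len(bits) - HEADER_BITS:
            raise TruncationError(
                f"declared payload of {payload_bits} bits exceeds the {len(bits) - HEADER_BITS}"
                " bits present"
            )
        bits = bits[HEADER_BITS : HEADER_BITS + payload_bits]
    else:
        bits = bits[: 8 * (len(bits) // 8)]
    return np.packbits(bits).tobytes() if len(bits) else b""


def realized_rate(payload: bytes, dna: str) -> float:
    """Payload bits per nucleotide of the full encoding (header overhead
    counts against the rate); tends to ``b/n`` for large payloads."""
    if not dna:
        raise ParameterError("empty encoding has no rate")
    return 8 * len(payload) / len(dna)
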