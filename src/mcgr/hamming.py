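"""Hamming-distance matrices on the mCGR grid.

Two flavours:

* :func:`hamming_to_word` -- the distance of one reference word ``s`` to
  every word of the same length, laid out on the ``2^n x 2^n`` grid via the
  recursion ``H(s)^n = 1^2 (x) H(s)^(n-1) + B^1(s_n) (x) 1^(2^(n-1))``,
  where ``B^1(x)`` is the 2x2 single-character mismatch matrix (0 at x's
  quadrant, 1 elsewhere) and ``s_n`` the last character.
* :func:`pairwise_table` -- the full ``4^n x 4^n`` table of distances
  between all pairs, built from the 4x4 all-ones-minus-identity generator
  by the same doubling recursion and then re-indexed so that word ``w`` is
  at index ``k = row * 2^n + col`` of its grid coordinate.  That makes row
  extraction from the table consistent with the flattened single-word
  matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .layout import DEFAULT_LAYOUT, NucleotideLayout, _check_alphabet, seq_to_coord

#: default cap for the single-word dense matrix (2^10 x 2^10)
HAMMING_WORD_CAP = 10
#: default cap for the pairwise table (4^6 x 4^6)
PAIRWISE_CAP = 6


@dataclass
class HammingMatrix:
    """Distances from ``word`` to every same-length word, on the grid."""

    order: int
    word: str
    values: np.ndarray


@dataclass
class PairwiseTable:
    """Dense ``4^n x 4^n`` distance table; word index ``k = row*2^n + col``."""

    word_length: int
    values: np.ndarray


def b1_matrix(nucleotide: str, layout: NucleotideLayout = DEFAULT_LAYOUT) -> np.ndarray:
    """Single-character mismatch matrix: 0 at the nucleotide's quadrant,
    1 elsewhere.

    >>> b1_matrix("A")
    array([[0, 1],
           [1, 1]], dtype=uint8)
    """
    _check_alphabet(nucleotide)
    if len(nucleotide) != 1:
        raise ParameterError("b1_matrix takes a single nucleotide")
    out = np.ones((2, 2), dtype=np.uint8)
    rb, cb = layout.corner_of[nucleotide]
    out[rb, cb] = 0
    return out


def hamming_to_word(
    s: str,
    layout: NucleotideLayout = DEFAULT_LAYOUT,
    *,
    cap: int = HAMMING_WORD_CAP,
) -> HammingMatrix:
    """Grid of Hamming distances from ``s`` to all words of ``len(s)``."""
    _check_alphabet(s)
    n = len(s)
    if not 1 <= n <= cap:
        raise ParameterError(f"word length {n} outside 1..{cap}")
    values = b1_matrix(s[0], layout)
    for k in range(2, n + 1):
        half = 1 << (k - 1)
        values = np.kron(np.ones((2, 2), dtype=np.uint8), values) + np.kron(
            b1_matrix(s[k - 1], layout), np.ones((half, half), dtype=np.uint8)
        )
    return HammingMatrix(n, s, values)


def word_index(seq: str, layout: NucleotideLayout = DEFAULT_LAYOUT) -> int:
    """Index of a word in the pairwise table: ``row * 2^n + col``."""
    coord = seq_to_coord(seq, layout)
    return coord.row * (1 << coord.order) + coord.col


def _natural_to_coord_permutation(n: int) -> np.ndarray:
    """Map coordinate index k = r*2^n + q  ->  the recursion's natural
    base-4 index (character digits coarse-to-fine, digit = 2*row_bit +
    col_bit)."""
    k = np.arange(1 << (2 * n), dtype=np.int64)
    q = k & ((1 << n) - 1)
    r = k >> n
    natural = np.zeros_like(k)
    for i in range(n):
        digit = (((r >> i) & 1) << 1) | ((q >> i) & 1)
        natural |= digit << (2 * i)
    return natural


def pairwise_table(n: int, *, cap: int = PAIRWISE_CAP) -> PairwiseTable:
    """All-pairs Hamming distance table for words of length ``n``.

    Built by ``T^n = 1^4 (x) T^(n-1) + T^1 (x) 1^(4^(n-1))`` with ``T^1``
    the 4x4 all-ones-minus-identity generator, then permuted from the
    recursion's per-character index to the grid index ``k = row*2^n + col``.
    The table does not depend on the corner layout (it is symmetric under
    relabelling), but the *indexing* uses the default layout's coordinates.
    """
    if not 1 <= n <= cap:
        raise ParameterError(f"n = {n} outside 1..{cap} (dense 4^n x 4^n guard)")
    t1 = (np.ones((4, 4)) - np.eye(4)).astype(np.uint8)
    values = t1
    for k in range(2, n + 1):
        quarter = 1 << (2 * (k - 1))
        values = np.kron(np.ones((4, 4), dtype=np.uint8), values) + np.kron(
            t1, np.ones((quarter, quarter), dtype=np.uint8)
        )
    perm = _natural_to_coord_permutation(n)
    values = values[np.ix_(perm, perm)]
    return PairwiseTable(n, values)
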