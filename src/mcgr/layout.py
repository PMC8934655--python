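"""Corner layouts and the word <-> grid-cell bijection.

A matrix chaos-game representation (mCGR) of order ``n`` is a ``2^n x 2^n``
grid whose cells are in bijection with the ``4^n`` DNA words of length
``n``.  Each nucleotide owns one quadrant of the unit cell, described by a
``(row_bit, col_bit)`` pair; a word's cell is obtained by interleaving the
bits of its characters.

Bit convention
--------------
Bit ``i`` (``i = 0`` least significant) of both the row and the column
index carries the ``(row_bit, col_bit)`` of character ``i + 1`` counted from
the *start* of the word.  The first character therefore selects the finest
subdivision and the last character the coarsest quadrant, so every coarse
quadrant shares its final letter -- the defining self-similarity of the
grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

from .errors import AlphabetError, BoundsError, ParameterError

NUCLEOTIDES = "ACGT"

#: Default hard cap on the word length / matrix order.  A dense 2^n x 2^n
#: byte matrix at n = 14 already needs ~270 MB; around 12 nt is the
#: practical limit for full enumeration.
WORD_LENGTH_CAP = 14


@dataclass(frozen=True)
class NucleotideLayout:
    """Assignment of the four nucleotides to the four grid quadrants.

    ``corner_of`` maps each nucleotide to its ``(row_bit, col_bit)`` pair;
    the mapping must be a bijection onto {0,1} x {0,1}.
    """

    corner_of: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: {"A": (0, 0), "T": (0, 1), "G": (1, 0), "C": (1, 1)}
    )

    def __post_init__(self) -> None:
        if set(self.corner_of) != set(NUCLEOTIDES):
            raise ParameterError(f"layout must cover exactly {{A,C,G,T}}, got {sorted(self.corner_of)}")
        corners = set(self.corner_of.values())
        if corners != {(0, 0), (0, 1), (1, 0), (1, 1)}:
            raise ParameterError(f"layout corners must be a bijection onto {{0,1}}^2, got {sorted(corners)}")

    @property
    def nucleotide_at(self) -> Dict[Tuple[int, int], str]:
        """Inverse mapping: corner -> nucleotide."""
        return {v: k for k, v in self.corner_of.items()}

    def grid(self) -> Tuple[Tuple[str, str], Tuple[str, str]]:
        """The layout as a 2x2 nested tuple, row-major."""
        inv = self.nucleotide_at
        return ((inv[(0, 0)], inv[(0, 1)]), (inv[(1, 0)], inv[(1, 1)]))


#: The standard layout [[A, T], [G, C]]: A top-left, T top-right,
#: G bottom-left, C bottom-right.
LAYOUT_AT_GC = NucleotideLayout()

#: Alternate layout [[A, C], [G, T]] (A/T on the diagonal), which produces
#: different GC-content patterns.
LAYOUT_AC_GT = NucleotideLayout({"A": (0, 0), "C": (0, 1), "G": (1, 0), "T": (1, 1)})

DEFAULT_LAYOUT = LAYOUT_AT_GC

LAYOUT_PRESETS = {"at-gc": LAYOUT_AT_GC, "ac-gt": LAYOUT_AC_GT}


@dataclass(frozen=True)
class Coordinate:
    """Position ``(row, col)`` of a word in the ``2^order`` grid."""

    row: int
    col: int
    order: int

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ParameterError(f"order must be >= 1, got {self.order}")
        size = 1 << self.order
        if not (0 <= self.row < size and 0 <= self.col < size):
            raise BoundsError(
                f"coordinate ({self.row}, {self.col}) outside the {size}x{size} grid of order {self.order}"
            )


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - set(NUCLEOTIDES)
    if bad:
        raise AlphabetError(f"invalid characters {sorted(bad)} in sequence {seq!r}; alphabet is A/C/G/T")


def seq_to_coord(seq: str, layout: NucleotideLayout = DEFAULT_LAYOUT) -> Coordinate:
    """Map a DNA word to its grid cell.

    The first character sets the least-significant bits of row and column,
    the last character the most-significant ones.

    >>> seq_to_coord("CC")
    Coordinate(row=3, col=3, order=2)
    """
    if not seq:
        raise AlphabetError("sequence must be non-empty")
    _check_alphabet(seq)
    row = col = 0
    for i, ch in enumerate(seq):
        rb, cb = layout.corner_of[ch]
        row |= rb << i
        col |= cb << i
    return Coordinate(row, col, len(seq))


def coord_to_seq(coord: Coordinate, layout: NucleotideLayout = DEFAULT_LAYOUT) -> str:
    """Back-calculate the DNA word stored at a grid cell (inverse of
    :func:`seq_to_coord`)."""
    inv = layout.nucleotide_at
    chars = []
    for i in range(coord.order):
        rb = (coord.row >> i) & 1
        cb = (coord.col >> i) & 1
        chars.append(inv[(rb, cb)])
    return "".join(chars)
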