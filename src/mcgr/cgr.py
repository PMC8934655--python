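"""Classic chaos game representation with exact rational arithmetic.

The CGR places the four nucleotides at the corners of the square
``[-1, 1] x [-1, 1]`` and iterates the midpoint rule from the origin: each
character moves the current point halfway towards its corner.  Coordinates
are kept as exact :class:`fractions.Fraction` values, so after ``k`` steps
every denominator divides ``2^k`` and no floating-point error accumulates.

Corner convention: the column bit of a nucleotide's layout quadrant maps to
the x-axis (0 -> -1, 1 -> +1) and the row bit to the y-axis (0 -> +1,
1 -> -1), i.e. matrix row 0 is the top of the square.  With the default
layout: A = (-1, +1), T = (+1, +1), G = (-1, -1), C = (+1, -1).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import List, Tuple

from .layout import DEFAULT_LAYOUT, NucleotideLayout, _check_alphabet


@dataclass(frozen=True)
class RationalPoint:
    """Exact point inside the unit square."""

    x: Fraction
    y: Fraction


def corner_point(nucleotide: str, layout: NucleotideLayout = DEFAULT_LAYOUT) -> Tuple[int, int]:
    """The (x, y) corner of a nucleotide, each in {-1, +1}."""
    _check_alphabet(nucleotide)
    rb, cb = layout.corner_of[nucleotide]
    return (1 if cb else -1, -1 if rb else 1)


def cgr_points(seq: str, layout: NucleotideLayout = DEFAULT_LAYOUT) -> List[RationalPoint]:
    """One exact midpoint per character, starting from the origin.

    >>> cgr_points("C")
    [RationalPoint(x=Fraction(1, 2), y=Fraction(-1, 2))]
    """
    _check_alphabet(seq)
    x = y = Fraction(0)
    points: List[RationalPoint] = []
    for ch in seq:
        cx, cy = corner_point(ch, layout)
        x = (x + cx) / 2
        y = (y + cy) / 2
        points.append(RationalPoint(x, y))
    return points
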