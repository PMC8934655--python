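"""User constraints: GC content, homopolymer runs, forbidden motifs.

GC content is handled through a dense matrix built by the same Kronecker
doubling recursion as the constraint matrices,

    D^n = 1^(2^(n-1)) (x) D^1  +  D^(n-1) (x) 1^2

with a layout-dependent 2x2 generator ``D^1`` holding a 1 in each quadrant
whose nucleotide is G or C.  The cell of every word then carries its G+C
count.  Homopolymer limits are reduced to four forbidden motifs: forbidding
``X^(r+1)`` for each nucleotide ``X`` forbids every run longer than ``r``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from Bio import SeqIO

from .errors import AlphabetError, ParameterError
from .layout import (
    DEFAULT_LAYOUT,
    NUCLEOTIDES,
    WORD_LENGTH_CAP,
    NucleotideLayout,
)

RationalLike = Union[Fraction, float, int, str]


def exact_fraction(value: RationalLike) -> Fraction:
    """Exact rational from user input.

    Floats go through their shortest decimal representation, so a bound
    written as ``0.4`` means exactly 2/5 rather than the nearest binary
    float (which is slightly larger and would wrongly exclude a GC count
    of exactly 40%).
    """
    if isinstance(value, float):
        return Fraction(str(value))
    return Fraction(value)


def _as_fraction(value: RationalLike, name: str) -> Fraction:
    frac = exact_fraction(value)
    if not 0 <= frac <= 1:
        raise ParameterError(f"{name} must lie in [0, 1], got {frac}")
    return frac


@dataclass(frozen=True)
class ConstraintSpec:
    """Everything needed to enumerate a codebook.

    ``gc_min``/``gc_max`` are fractions in [0, 1] (``None`` = unconstrained,
    bounds inclusive); ``max_homopolymer`` is the longest *allowed* run
    (``None`` = unconstrained); ``motifs`` are forbidden substrings.
    """

    word_length: int
    gc_min: Optional[Fraction] = None
    gc_max: Optional[Fraction] = None
    max_homopolymer: Optional[int] = None
    motifs: Tuple[str, ...] = ()
    layout: NucleotideLayout = field(default=DEFAULT_LAYOUT)

    def __post_init__(self) -> None:
        if self.word_length < 1:
            raise ParameterError(f"word_length must be >= 1, got {self.word_length}")
        for name in ("gc_min", "gc_max"):
            val = getattr(self, name)
            if val is not None:
                object.__setattr__(self, name, _as_fraction(val, name))
        if self.gc_min is not None and self.gc_max is not None and self.gc_min > self.gc_max:
            raise ParameterError(f"gc_min {self.gc_min} > gc_max {self.gc_max}")
        if self.max_homopolymer is not None and self.max_homopolymer < 1:
            raise ParameterError(f"max_homopolymer must be >= 1, got {self.max_homopolymer}")
        motifs = tuple(m.upper() for m in self.motifs)
        for m in motifs:
            bad = set(m) - set(NUCLEOTIDES)
            if not m or bad:
                raise AlphabetError(f"invalid motif {m!r}")
            if len(m) > self.word_length:
                raise ParameterError(
                    f"motif {m!r} is longer than the word length {self.word_length}"
                )
        object.__setattr__(self, "motifs", motifs)

    def forbidden_motifs(self) -> Tuple[str, ...]:
        """Explicit motifs plus the homopolymer motifs, deduplicated."""
        motifs = list(self.motifs)
        if self.max_homopolymer is not None:
            for m in homopolymer_motifs(self.max_homopolymer):
                if m not in motifs:
                    motifs.append(m)
        return tuple(motifs)


def homopolymer_motifs(max_run: int) -> List[str]:
    """The four shortest forbidden runs ``X^(max_run+1)``.

    >>> homopolymer_motifs(2)
    ['AAA', 'CCC', 'GGG', 'TTT']
    """
    if max_run < 1:
        raise ParameterError(f"max_run must be >= 1, got {max_run}")
    return [x * (max_run + 1) for x in sorted(NUCLEOTIDES)]


@dataclass
class GcMatrix:
    """Dense ``2^n x 2^n`` grid of per-word G+C counts."""

    order: int
    values: np.ndarray

    def __post_init__(self) -> None:
        size = 1 << self.order
        if self.values.shape != (size, size):
            raise ParameterError(
                f"values shape {self.values.shape} does not match order {self.order}"
            )


def gc_generator(layout: NucleotideLayout = DEFAULT_LAYOUT) -> np.ndarray:
    """Layout-dependent 2x2 generator: 1 where the quadrant's nucleotide is
    G or C ([[0,0],[1,1]] for [[A,T],[G,C]]; [[0,1],[1,0]] for [[A,C],[G,T]])."""
    d1 = np.zeros((2, 2), dtype=np.uint8)
    for nuc, (rb, cb) in layout.corner_of.items():
        if nuc in "GC":
            d1[rb, cb] = 1
    return d1


def gc_count_matrix(
    n: int,
    layout: NucleotideLayout = DEFAULT_LAYOUT,
    *,
    cap: int = WORD_LENGTH_CAP,
) -> GcMatrix:
    """Build the GC-count matrix by the doubling recursion."""
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if n > cap:
        raise ParameterError(f"order {n} exceeds the dense cap of {cap}")
    d1 = gc_generator(layout)
    values = d1.astype(np.uint8)
    for k in range(2, n + 1):
        half = 1 << (k - 1)
        values = np.kron(np.ones((half, half), dtype=np.uint8), d1) + np.kron(
            values, np.ones((2, 2), dtype=np.uint8)
        )
    return GcMatrix(n, values)


def gc_allowed(
    gc_count: int,
    n: int,
    gc_min: Optional[RationalLike] = None,
    gc_max: Optional[RationalLike] = None,
) -> bool:
    """Inclusive interval test ``gc_min <= gc_count/n <= gc_max`` in exact
    rational arithmetic; an unset bound is unbounded."""
    if not 0 <= gc_count <= n:
        raise ParameterError(f"gc_count {gc_count} outside [0, {n}]")
    frac = Fraction(gc_count, n)
    if gc_min is not None and frac < exact_fraction(gc_min):
        return False
    if gc_max is not None and frac > exact_fraction(gc_max):
        return False
    return True


def load_motifs(path) -> List[str]:
    """Read forbidden motifs from a plain FASTA file.

    Sequences are upper-cased and must be strict A/C/G/T; duplicates are
    dropped while preserving the original order.
    """
    motifs: List[str] = []
    seen = set()
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - set(NUCLEOTIDES)
        if not seq or bad:
            raise AlphabetError(
                f"record {record.id!r}: invalid characters {sorted(bad) or '(empty)'};"
                " motifs must be plain A/C/G/T"
            )
        if seq not in seen:
            seen.add(seq)
            motifs.append(seq)
    if not motifs:
        warnings.warn(f"no motifs found in {path}", stacklevel=2)
    return motifs
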