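"""Sparse constraint matrices and the fractal doubling recursion.

A :class:`ConstraintMatrix` of order ``n`` stores, for each grid cell that
is affected at all, how many times the forbidden substring(s) occur in the
length-``n`` word at that cell.  Cells that are absent have count zero and
correspond to allowed words.  Only affected positions are stored -- the
allowed set is recovered as the complement.

Going from order ``n`` to ``n + 1`` is the "tile + stretch + add" step.
Two elementary sparse maps mirror the two Kronecker products with the 2x2
matrix of ones:

* **tiling** (``1 (x) M``): every entry ``(r, q)`` reappears at the four
  cells ``(r + b*2^n, q + c*2^n)`` -- the word gains one arbitrary
  character at the *end* (coarse bits);
* **stretching** (``M (x) 1``): every entry reappears at
  ``(2r + b, 2q + c)`` -- the word gains one arbitrary character at the
  *start* (the old bits shift up by one).

Counting convention.  Tiling the count matrix and stretching it again
would count *derivation paths* rather than occurrences: an occurrence
strictly inside a longer word would be reached once per interleaving of
the prepend/append steps.  To keep exact occurrence counts the matrix
carries a companion *suffix indicator* ``S`` (cells of words that end with
the motif).  One doubling step is then

    S^(n+1) = stretch(S^n)            (the motif stays glued to the end)
    M^(n+1) = tile(M^n) + S^(n+1)     (old occurrences + the new one that
                                       finishes at the appended character)

which reduces to the plain tile+stretch+add of the count matrix itself on
the first step from the motif's own order, and flags exactly the same
cells as the 0/1 formulation at every order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Optional, Tuple

import numpy as np

from .errors import ParameterError
from .layout import (
    DEFAULT_LAYOUT,
    WORD_LENGTH_CAP,
    Coordinate,
    NucleotideLayout,
    seq_to_coord,
)

_Entries = Dict[Tuple[int, int], int]


def _validate_entries(entries: _Entries, order: int, label: str) -> None:
    size = 1 << order
    for (r, q), c in entries.items():
        if c < 1:
            raise ParameterError(f"{label} counts must be >= 1, got {c} at ({r}, {q})")
        if not (0 <= r < size and 0 <= q < size):
            raise ParameterError(f"{label} entry ({r}, {q}) outside grid of order {order}")


@dataclass
class ConstraintMatrix:
    """Sparse map (row, col) -> number of forbidden-substring occurrences.

    All stored counts are >= 1; an absent cell means count 0 (allowed).
    ``suffix_counts`` is the companion indicator of cells whose word *ends*
    with a forbidden motif; when ``None`` (a matrix at the motif's own
    order, or any hand-built one) the counts themselves play that role.
    """

    order: int
    counts: _Entries = field(default_factory=dict)
    suffix_counts: Optional[_Entries] = None

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ParameterError(f"order must be >= 1, got {self.order}")
        _validate_entries(self.counts, self.order, "matrix")
        if self.suffix_counts is not None:
            _validate_entries(self.suffix_counts, self.order, "suffix")

    def effective_suffix(self) -> _Entries:
        return self.counts if self.suffix_counts is None else self.suffix_counts

    def get(self, coord: Coordinate) -> int:
        if coord.order != self.order:
            raise ParameterError(f"coordinate order {coord.order} != matrix order {self.order}")
        return self.counts.get((coord.row, coord.col), 0)

    def __len__(self) -> int:
        return len(self.counts)

    def flagged(self) -> Iterator[Coordinate]:
        """Iterate over the affected cells."""
        for r, q in self.counts:
            yield Coordinate(r, q, self.order)

    def copy(self) -> "ConstraintMatrix":
        return ConstraintMatrix(
            self.order,
            dict(self.counts),
            None if self.suffix_counts is None else dict(self.suffix_counts),
        )


def _to_arrays(entries: _Entries) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    m = len(entries)
    rows = np.fromiter((r for r, _ in entries), dtype=np.int64, count=m)
    cols = np.fromiter((q for _, q in entries), dtype=np.int64, count=m)
    vals = np.fromiter(entries.values(), dtype=np.int64, count=m)
    return rows, cols, vals


def _aggregate(rows: np.ndarray, cols: np.ndarray, vals: np.ndarray, new_order: int) -> _Entries:
    key = (rows << new_order) | cols
    uniq, inverse = np.unique(key, return_inverse=True)
    sums = np.zeros(len(uniq), dtype=np.int64)
    np.add.at(sums, inverse, vals)
    mask = (1 << new_order) - 1
    return {(int(k >> new_order), int(k & mask)): int(v) for k, v in zip(uniq, sums)}


def _stretch(entries: _Entries, order: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """M (x) 1: prepend an arbitrary character (shift bits up)."""
    rows, cols, vals = _to_arrays(entries)
    out_r = [2 * rows + b for b in (0, 1) for _ in (0, 1)]
    out_q = [2 * cols + c for _ in (0, 1) for c in (0, 1)]
    return np.concatenate(out_r), np.concatenate(out_q), np.tile(vals, 4)


def _tile(entries: _Entries, order: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """1 (x) M: append an arbitrary character (add coarse bits)."""
    size = 1 << order
    rows, cols, vals = _to_arrays(entries)
    out_r = [rows + b * size for b in (0, 1) for _ in (0, 1)]
    out_q = [cols + c * size for _ in (0, 1) for c in (0, 1)]
    return np.concatenate(out_r), np.concatenate(out_q), np.tile(vals, 4)


def extend_constraint(matrix: ConstraintMatrix) -> ConstraintMatrix:
    """One doubling step: order ``n`` -> ``n + 1``.

    The count at every cell of the result equals the number of (possibly
    overlapping) occurrences of the original motif(s), provided the input
    was produced by :func:`motif_matrix` / :func:`add_matrices` or sits at
    the motif's own order.
    """
    n = matrix.order
    if not matrix.counts:
        return ConstraintMatrix(n + 1, {}, {})
    sr, sq, sv = _stretch(matrix.effective_suffix(), n)
    new_suffix = _aggregate(sr, sq, sv, n + 1)
    tr, tq, tv = _tile(matrix.counts, n)
    new_counts = _aggregate(
        np.concatenate([tr, sr]), np.concatenate([tq, sq]), np.concatenate([tv, sv]), n + 1
    )
    return ConstraintMatrix(n + 1, new_counts, new_suffix)


def motif_matrix(
    motif: str,
    n: int,
    layout: NucleotideLayout = DEFAULT_LAYOUT,
    *,
    cap: int = WORD_LENGTH_CAP,
) -> ConstraintMatrix:
    """Occurrence-count matrix of a single motif at order ``n``.

    The cell of every length-``n`` word carries the number of (possibly
    overlapping) occurrences of ``motif`` in that word; words free of the
    motif are absent.
    """
    if n > cap:
        raise ParameterError(f"order {n} exceeds the cap of {cap}; pass a larger cap to override")
    if not 1 <= len(motif) <= n:
        raise ParameterError(f"motif length {len(motif)} must be between 1 and n = {n}")
    coord = seq_to_coord(motif, layout)
    matrix = ConstraintMatrix(len(motif), {(coord.row, coord.col): 1})
    for _ in range(n - len(motif)):
        matrix = extend_constraint(matrix)
    return matrix


def add_matrices(a: ConstraintMatrix, b: ConstraintMatrix) -> ConstraintMatrix:
    """Entrywise sum of two matrices of equal order (constraint union);
    both the counts and the suffix indicators add."""
    if a.order != b.order:
        raise ParameterError(f"order mismatch: {a.order} != {b.order}")
    counts = dict(a.counts)
    for key, v in b.counts.items():
        counts[key] = counts.get(key, 0) + v
    suffix = dict(a.effective_suffix())
    for key, v in b.effective_suffix().items():
        suffix[key] = suffix.get(key, 0) + v
    return ConstraintMatrix(a.order, counts, suffix)
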