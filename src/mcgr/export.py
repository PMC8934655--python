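"""Dense matrix export as CSV or ASCII PGM (P2).

Replaces interactive plotting: a constraint export writes per-cell
occurrence counts (0 = allowed word), so the fractal patterns -- the
Sierpinski triangle for a single forbidden letter, the T-square for other
motifs -- can be confirmed directly from the text output.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .constraint import add_matrices, motif_matrix
from .constraints import gc_count_matrix
from .errors import ParameterError
from .hamming import hamming_to_word
from .layout import DEFAULT_LAYOUT, NucleotideLayout

DENSE_EXPORT_CAP = 8


def constraint_grid(
    motifs: Sequence[str], n: int, layout: NucleotideLayout = DEFAULT_LAYOUT
) -> np.ndarray:
    """Dense occurrence-count grid for a set of motifs."""
    if n > DENSE_EXPORT_CAP:
        raise ParameterError(f"n = {n} exceeds the dense export cap of {DENSE_EXPORT_CAP}")
    if not motifs:
        raise ParameterError("at least one motif is required")
    matrix = None
    for m in motifs:
        mm = motif_matrix(m, n, layout)
        matrix = mm if matrix is None else add_matrices(matrix, mm)
    grid = np.zeros((1 << n, 1 << n), dtype=np.int64)
    for (r, q), c in matrix.counts.items():
        grid[r, q] = c
    return grid


def gc_grid(n: int, layout: NucleotideLayout = DEFAULT_LAYOUT) -> np.ndarray:
    if n > DENSE_EXPORT_CAP:
        raise ParameterError(f"n = {n} exceeds the dense export cap of {DENSE_EXPORT_CAP}")
    return gc_count_matrix(n, layout).values.astype(np.int64)


def hamming_grid(word: str, layout: NucleotideLayout = DEFAULT_LAYOUT) -> np.ndarray:
    if len(word) > DENSE_EXPORT_CAP:
        raise ParameterError(f"word length {len(word)} exceeds the dense export cap of {DENSE_EXPORT_CAP}")
    return hamming_to_word(word, layout).values.astype(np.int64)


def to_csv(grid: np.ndarray) -> str:
    return "\n".join(",".join(str(v) for v in row) for row in grid) + "\n"


def to_pgm(grid: np.ndarray) -> str:
    """ASCII (P2) grayscale; cell values are emitted verbatim, with the
    true maximum as the declared maxval, so the output is bit-exact and
    deterministic."""
    maxval = max(1, int(grid.max()))
    rows = "\n".join(" ".join(str(v) for v in row) for row in grid)
    return f"P2\n{grid.shape[1]} {grid.shape[0]}\n{maxval}\n{rows}\n"
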