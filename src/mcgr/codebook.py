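"""Codebook assembly, concatenation-safe pruning, code rate and FASTA I/O.

A codebook is the lexicographically sorted set of all words of a fixed
length that satisfy a :class:`~mcgr.constraints.ConstraintSpec`.  The
forbidden set is built once as a sparse constraint matrix (sum of the motif
matrices of all forbidden motifs, including the homopolymer motifs); the
allowed words are the complement cells that also pass the GC filter, and
their sequences are recovered by the back-calculation from grid
coordinates.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constraint import add_matrices, motif_matrix
from .constraints import ConstraintSpec, gc_allowed, gc_count_matrix
from .errors import AlphabetError, ParameterError
from .layout import NUCLEOTIDES, DEFAULT_LAYOUT, NucleotideLayout

logger = logging.getLogger(__name__)

#: default enumeration cap: 4^12 ~= 1.7e7 cells is the practical limit for
#: full enumeration on a workstation
ENUMERATION_CAP = 12


@dataclass
class Codebook:
    """Sorted list of allowed words plus the spec that produced it."""

    word_length: int
    words: List[str]
    spec: Optional[ConstraintSpec] = None

    def __post_init__(self) -> None:
        for w in self.words:
            if len(w) != self.word_length:
                raise ParameterError(
                    f"word {w!r} has length {len(w)}, expected {self.word_length}"
                )
        if any(a >= b for a, b in zip(self.words, self.words[1:])):
            raise ParameterError("codebook words must be strictly sorted (A<C<G<T)")

    def __len__(self) -> int:
        return len(self.words)


def _lexicographic_rank_lut(layout: NucleotideLayout) -> np.ndarray:
    """Per-quadrant letter rank (A=0 < C=1 < G=2 < T=3), indexed by
    ``2*row_bit + col_bit``."""
    lut = np.zeros(4, dtype=np.int64)
    for nuc, (rb, cb) in layout.corner_of.items():
        lut[(rb << 1) | cb] = sorted(NUCLEOTIDES).index(nuc)
    return lut


def _coords_to_sorted_words(
    rows: np.ndarray, cols: np.ndarray, n: int, layout: NucleotideLayout
) -> List[str]:
    """Back-calculate sequences for many cells at once, sorted A<C<G<T."""
    lut = _lexicographic_rank_lut(layout)
    count = len(rows)
    digits = np.empty((count, n), dtype=np.int64)
    for i in range(n):
        quad = (((rows >> i) & 1) << 1) | ((cols >> i) & 1)
        digits[:, i] = lut[quad]
    # char 0 is the most significant position in lexicographic order
    weights = 4 ** np.arange(n - 1, -1, -1, dtype=np.int64)
    keys = digits @ weights
    order = np.argsort(keys, kind="stable")
    codes = np.frombuffer(b"ACGT", dtype=np.uint8)[digits[order]]
    blob = codes.tobytes()
    return [blob[i * n : (i + 1) * n].decode("ascii") for i in range(count)]


def build_codebook(spec: ConstraintSpec, *, cap: int = ENUMERATION_CAP) -> Codebook:
    """Enumerate every word satisfying ``spec``.

    Raises on ``word_length`` beyond the cap; a contradictory spec yields an
    empty codebook with a warning rather than an error.
    """
    n = spec.word_length
    if n > cap:
        raise ParameterError(
            f"word length {n} exceeds the enumeration cap of {cap} "
            f"(4^{n} cells); pass cap={n} to override if you have the memory"
        )
    size = 1 << n
    allowed = np.ones((size, size), dtype=bool)

    if spec.gc_min is not None or spec.gc_max is not None:
        gc = gc_count_matrix(n, spec.layout, cap=max(cap, n)).values
        ok_count = np.array(
            [gc_allowed(k, n, spec.gc_min, spec.gc_max) for k in range(n + 1)]
        )
        allowed &= ok_count[gc]

    forbidden = None
    for m in spec.forbidden_motifs():
        if len(m) > n:
            continue  # cannot occur in a word this short
        mm = motif_matrix(m, n, spec.layout, cap=max(cap, n))
        forbidden = mm if forbidden is None else add_matrices(forbidden, mm)
    if forbidden is not None and forbidden.counts:
        fr = np.fromiter((r for r, _ in forbidden.counts), dtype=np.int64, count=len(forbidden))
        fq = np.fromiter((q for _, q in forbidden.counts), dtype=np.int64, count=len(forbidden))
        allowed[fr, fq] = False

    rows, cols = np.nonzero(allowed)
    if len(rows) == 0:
        warnings.warn("constraints are contradictory: the codebook is empty", stacklevel=2)
        return Codebook(n, [], spec)
    words = _coords_to_sorted_words(rows.astype(np.int64), cols.astype(np.int64), n, spec.layout)
    book = Codebook(n, words, spec)
    logger.info("codebook: %d words of length %d, code rate %.4f", len(book), n, code_rate(book))
    return book


def concat_safe_filter(book: Codebook, motifs: Sequence[str]) -> Codebook:
    """Drop words that could complete a forbidden motif across a junction.

    For each motif ``m`` of length ``L`` and every ``k`` with
    ``ceil(L/2) <= k <= L-1``, a word is removed if its length-``k`` suffix
    equals ``m[:k]`` or its length-``k`` prefix equals ``m[L-k:]``.

    Why this suffices: a motif occurrence spanning the junction of words
    ``u | v`` splits ``m`` into a suffix part of ``u`` of length ``k`` and a
    prefix part of ``v`` of length ``L - k``; since
    ``max(k, L-k) >= ceil(L/2)``, at least one side carries a half-or-longer
    terminal match and is removed.  Surviving words can therefore be
    concatenated in any order without creating a motif at the boundary.
    """
    n = book.word_length
    suffixes: dict[int, set] = {}
    prefixes: dict[int, set] = {}
    for m in motifs:
        length = len(m)
        if length > n:
            raise ParameterError(f"motif {m!r} longer than the word length {n}")
        for k in range(math.ceil(length / 2), length):
            suffixes.setdefault(k, set()).add(m[:k])
            prefixes.setdefault(k, set()).add(m[length - k :])

    def survives(w: str) -> bool:
        for k, ends in suffixes.items():
            if w[n - k :] in ends:
                return False
        for k, starts in prefixes.items():
            if w[:k] in starts:
                return False
        return True

    kept = [w for w in book.words if survives(w)]
    logger.info("concat-safe filter: %d -> %d words", len(book), len(kept))
    return Codebook(n, kept, book.spec)


def code_rate(book: Codebook) -> float:
    """Information per nucleotide, ``log2(|C|) / n`` (max 2 bits/nt)."""
    if len(book) < 1:
        raise ParameterError("code rate is undefined for an empty codebook")
    return math.log2(len(book)) / book.word_length


def write_codebook(book: Codebook, path) -> None:
    """Write one word per FASTA record with sequential IDs w000001..."""
    records = (
        SeqRecord(Seq(w), id=f"w{i + 1:06d}", description="")
        for i, w in enumerate(book.words)
    )
    SeqIO.write(records, str(path), "fasta")


def read_codebook(path) -> Codebook:
    """Read a codebook FASTA; validates uniform length and alphabet, sorts
    (with a notice) if the file was unsorted, and drops duplicates."""
    words: List[str] = []
    length: Optional[int] = None
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - set(NUCLEOTIDES)
        if not seq or bad:
            raise AlphabetError(f"record {record.id!r}: invalid codebook word {seq!r}")
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ParameterError(
                f"record {record.id!r}: mixed word lengths ({len(seq)} vs {length})"
            )
        words.append(seq)
    if length is None:
        raise ParameterError(f"no records found in {path}")
    deduped = sorted(set(words))
    if deduped != words:
        warnings.warn(f"codebook {path} was unsorted or contained duplicates; normalised", stacklevel=2)
    return Codebook(length, deduped)
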