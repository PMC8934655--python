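"""Independent brute-force references and seeded fixture generation.

Everything here works by direct string scanning over exhaustive
enumerations and shares no code path with the matrix recursions it is used
to check, so agreement between the two routes is meaningful evidence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .codebook import Codebook, write_codebook
from .constraints import ConstraintSpec
from .errors import ParameterError

BRUTE_FORCE_CAP = 8


def all_words(n: int) -> List[str]:
    """All 4^n words of length ``n`` in A<C<G<T order."""
    if n > BRUTE_FORCE_CAP:
        raise ParameterError(f"n = {n} exceeds the brute-force cap of {BRUTE_FORCE_CAP}")
    return ["".join(p) for p in itertools.product("ACGT", repeat=n)]


def max_run(word: str) -> int:
    longest = run = 1
    for a, b in zip(word, word[1:]):
        run = run + 1 if a == b else 1
        longest = max(longest, run)
    return longest


def brute_force_occurrences(word: str, motifs: Sequence[str]) -> int:
    """Total count of (possibly overlapping) occurrences of all motifs."""
    total = 0
    for m in motifs:
        total += sum(1 for i in range(len(word) - len(m) + 1) if word[i : i + len(m)] == m)
    return total


def brute_force_codebook(spec: ConstraintSpec) -> List[str]:
    """Direct string-filter enumeration of the allowed words (n <= 8)."""
    n = spec.word_length
    motifs = [m for m in spec.motifs if len(m) <= n]
    keep: List[str] = []
    for w in all_words(n):
        if spec.max_homopolymer is not None and max_run(w) > spec.max_homopolymer:
            continue
        if any(m in w for m in motifs):
            continue
        gc = Fraction(sum(c in "GC" for c in w), n)
        if spec.gc_min is not None and gc < spec.gc_min:
            continue
        if spec.gc_max is not None and gc > spec.gc_max:
            continue
        keep.append(w)
    return keep


@dataclass(frozen=True)
class FixtureSpec:
    """Seeded description of a reproducible fixture set.

    Defaults mirror the benchmark conditions: length-10 words, GC 40-60%,
    homopolymer runs of at most 3, and seven random payload blobs with the
    sizes of the original jpg corpus (300 kB to 1.7 MB).
    """

    seed: int
    word_length: int = 10
    gc_min: Optional[Fraction] = Fraction(2, 5)
    gc_max: Optional[Fraction] = Fraction(3, 5)
    max_homopolymer: Optional[int] = 3
    motif_count: int = 3
    motif_length_range: Tuple[int, int] = (4, 6)
    payload_sizes: Tuple[int, ...] = (
        300_000, 533_000, 767_000, 1_000_000, 1_233_000, 1_467_000, 1_700_000,
    )


def random_motifs(rng: np.random.Generator, count: int, length_range: Tuple[int, int]) -> List[str]:
    motifs = []
    lo, hi = length_range
    while len(motifs) < count:
        length = int(rng.integers(lo, hi + 1))
        m = "".join(rng.choice(list("ACGT"), size=length))
        if m not in motifs:
            motifs.append(m)
    return motifs


def make_fixtures(fs: FixtureSpec, outdir) -> dict:
    """Write a motif FASTA, a generated codebook and random payload blobs.

    Identical seeds produce byte-identical files.  Returns the paths.
    """
    from .codebook import build_codebook  # local import to keep module load light

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(fs.seed)

    motifs = random_motifs(rng, fs.motif_count, fs.motif_length_range)
    motif_path = out / "motifs.fasta"
    with open(motif_path, "w") as fh:
        for i, m in enumerate(motifs):
            fh.write(f">m{i + 1}\n{m}\n")

    spec = ConstraintSpec(
        word_length=fs.word_length,
        gc_min=fs.gc_min,
        gc_max=fs.gc_max,
        max_homopolymer=fs.max_homopolymer,
        motifs=tuple(motifs),
    )
    book = build_codebook(spec)
    book_path = out / "codebook.fasta"
    write_codebook(book, book_path)

    payload_paths = []
    for i, size in enumerate(fs.payload_sizes):
        p = out / f"payload_{i:02d}.bin"
        p.write_bytes(rng.bytes(size))
        payload_paths.append(p)

    return {"motifs": motif_path, "codebook": book_path, "payloads": payload_paths}
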