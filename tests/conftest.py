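import functools
from fractions import Fraction

import pytest

from mcgr import ConstraintSpec, build_codebook, concat_safe_filter
from mcgr.oracles import all_words


@pytest.fixture(scope="session")
def words_of():
    """Cached exhaustive word lists: words_of(n) -> all 4^n words."""
    return functools.lru_cache(maxsize=None)(lambda n: all_words(n))


@pytest.fixture(scope="session")
def benchmark_spec():
    """The benchmark constraint set: length-10 words, GC 40-60 percent,
    homopolymer runs of at most 3, no additional motifs."""
    return ConstraintSpec(
        word_length=10,
        gc_min=Fraction(2, 5),
        gc_max=Fraction(3, 5),
        max_homopolymer=3,
    )


@pytest.fixture(scope="session")
def benchmark_codebook(benchmark_spec):
    """Concatenation-safe lexicographic codebook under the benchmark
    constraints (built once per session)."""
    book = build_codebook(benchmark_spec)
    return concat_safe_filter(book, benchmark_spec.forbidden_motifs())
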