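"""Codebook enumeration, concatenation-safe pruning, rate, FASTA I/O."""

import math
from fractions import Fraction

import pytest

from mcgr import (
    AlphabetError,
    Codebook,
    ConstraintSpec,
    ParameterError,
    build_codebook,
    code_rate,
    concat_safe_filter,
    read_codebook,
    write_codebook,
)
from mcgr.oracles import brute_force_codebook, max_run


def test_no_adjacent_repeats_count():
    book = build_codebook(ConstraintSpec(2, max_homopolymer=1))
    assert len(book) == 12


def test_single_motif_count():
    book = build_codebook(ConstraintSpec(3, motifs=("CC",)))
    assert len(book) == 57  # 64 - 7 words containing CC
    assert all("CC" not in w for w in book.words)


def test_even_length_narrow_gc_forces_exact_half():
    book = build_codebook(ConstraintSpec(6, gc_min=Fraction(2, 5), gc_max=Fraction(3, 5)))
    assert all(sum(c in "GC" for c in w) == 3 for w in book.words)


def test_words_are_sorted_and_satisfy_spec():
    spec = ConstraintSpec(5, gc_min="0.4", gc_max="0.6", max_homopolymer=2, motifs=("ACG",))
    book = build_codebook(spec)
    assert book.words == sorted(book.words)
    for w in book.words:
        assert "ACG" not in w and max_run(w) <= 2
        assert Fraction(2, 5) <= Fraction(sum(c in "GC" for c in w), 5) <= Fraction(3, 5)


def test_matches_brute_force_enumeration():
    spec = ConstraintSpec(6, gc_min=0.4, gc_max=0.6, max_homopolymer=2, motifs=("GCGC", "TA"))
    assert build_codebook(spec).words == brute_force_codebook(spec)


def test_alternate_layout_gives_same_word_set():
    from mcgr import LAYOUT_AC_GT

    spec_a = ConstraintSpec(4, gc_min=0.5, gc_max=0.5, max_homopolymer=2)
    spec_b = ConstraintSpec(4, gc_min=0.5, gc_max=0.5, max_homopolymer=2, layout=LAYOUT_AC_GT)
    assert build_codebook(spec_a).words == build_codebook(spec_b).words


def test_monotonicity():
    base = build_codebook(ConstraintSpec(5, max_homopolymer=2))
    with_motif = build_codebook(ConstraintSpec(5, max_homopolymer=2, motifs=("ACG",)))
    assert len(with_motif) <= len(base)
    narrow = build_codebook(ConstraintSpec(5, gc_min=0.4, gc_max=0.6))
    wide = build_codebook(ConstraintSpec(5, gc_min=0.2, gc_max=0.8))
    assert len(wide) >= len(narrow)


def test_contradictory_spec_warns_empty():
    with pytest.warns(UserWarning):
        book = build_codebook(ConstraintSpec(2, motifs=("A", "C", "G", "T")))
    assert len(book) == 0
    with pytest.raises(ParameterError):
        code_rate(book)


def test_enumeration_cap():
    with pytest.raises(ParameterError, match="cap"):
        build_codebook(ConstraintSpec(13))


def test_concat_safe_homopolymer_example():
    """For motif AAA, exactly the words ending with AA or starting with AA
    are removed; TAAT survives."""
    book = build_codebook(ConstraintSpec(4, motifs=("AAA",)))
    safe = concat_safe_filter(book, ["AAA"])
    removed = set(book.words) - set(safe.words)
    assert removed == {w for w in book.words if w.endswith("AA") or w.startswith("AA")}
    assert "TAAT" in safe.words


def test_concat_safe_junction_property():
    """Every ordered pair of surviving words concatenates without creating
    a motif occurrence anywhere, including across the junction."""
    motifs = ["AAA", "CGCG"]
    book = build_codebook(ConstraintSpec(4, motifs=tuple(motifs)))
    safe = concat_safe_filter(book, motifs)
    assert set(safe.words) <= set(book.words)
    for u in safe.words:
        for v in safe.words:
            joined = u + v
            assert all(m not in joined for m in motifs)


def test_code_rate():
    full = Codebook(2, sorted("".join((a, b)) for a in "ACGT" for b in "ACGT"))
    assert code_rate(full) == pytest.approx(2.0)
    assert code_rate(Codebook(3, ["ACG"])) == 0.0
    # a 484263-word codebook of length 10 carries log2(484263)/10 bits/nt
    assert math.log2(484263) / 10 == pytest.approx(1.8885, abs=1e-4)


def test_fasta_round_trip(tmp_path):
    book = build_codebook(ConstraintSpec(3, max_homopolymer=1))
    path = tmp_path / "book.fasta"
    write_codebook(book, path)
    back = read_codebook(path)
    assert back.words == book.words and back.word_length == 3


def test_fasta_read_normalises_unsorted(tmp_path):
    path = tmp_path / "unsorted.fasta"
    path.write_text(">a\nTTT\n>b\nAAA\n>c\nAAA\n")
    with pytest.warns(UserWarning):
        book = read_codebook(path)
    assert book.words == ["AAA", "TTT"]


def test_fasta_read_rejects_bad_input(tmp_path):
    mixed = tmp_path / "mixed.fasta"
    mixed.write_text(">a\nAAA\n>b\nCCCC\n")
    with pytest.raises(ParameterError):
        read_codebook(mixed)
    bad = tmp_path / "bad.fasta"
    bad.write_text(">a\nAXA\n")
    with pytest.raises(AlphabetError):
        read_codebook(bad)
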