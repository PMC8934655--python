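"""Lexicographic binary <-> DNA codec."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcgr import (
    Codebook,
    ConstraintSpec,
    CorruptionError,
    DecodeError,
    FramingError,
    ParameterError,
    TruncationError,
    block_size,
    build_codebook,
    decode,
    encode,
    realized_rate,
)
from mcgr.codec import HEADER_BITS

SINGLE = Codebook(1, ["A", "C", "G", "T"])


@pytest.fixture(scope="module")
def small_book():
    """339-word book of length 4 (b = 8): exercises partial-block padding."""
    return build_codebook(ConstraintSpec(4, max_homopolymer=2, motifs=("CG",)))


def test_block_size():
    assert block_size(484263) == 18
    assert block_size(4) == 2
    assert block_size(2**13) == 13
    assert block_size(3) == 1
    with pytest.raises(ParameterError):
        block_size(1)


def test_identity_indexing_without_header():
    """With the codebook {A,C,G,T} the 2-bit blocks index the alphabet
    directly: bits 00 01 10 11 -> ACGT."""
    assert encode(bytes([0b00011011]), SINGLE, with_header=False) == "ACGT"
    assert decode("ACGT", SINGLE, with_header=False) == bytes([0b00011011])


def test_header_only_encoding():
    dna = encode(b"", SINGLE)
    assert len(dna) == math.ceil(HEADER_BITS / 2)  # b = 2, n = 1
    assert decode(dna, SINGLE) == b""


@pytest.mark.parametrize("size", [0, 1, 2, 17, 255, 4096])
def test_round_trip_sizes(size, small_book):
    rng = np.random.default_rng(size)
    payload = rng.bytes(size)
    dna = encode(payload, small_book)
    assert len(dna) % small_book.word_length == 0
    assert decode(dna, small_book) == payload


@given(payload=st.binary(max_size=400))
@settings(max_examples=150, deadline=None)
def test_round_trip_property(payload):
    book = build_codebook(ConstraintSpec(2, max_homopolymer=1))  # 12 words, b = 3
    assert decode(encode(payload, book), book) == payload


def test_emitted_words_are_addressable(small_book):
    b = block_size(len(small_book))
    addressable = set(small_book.words[: 1 << b])
    dna = encode(bytes(range(256)), small_book)
    n = small_book.word_length
    words = {dna[i : i + n] for i in range(0, len(dna), n)}
    assert words <= addressable


def test_framing_error(small_book):
    dna = encode(b"hi", small_book)
    with pytest.raises(FramingError):
        decode(dna[:-1], small_book)


def test_unknown_word_offset(small_book):
    dna = encode(b"hi", small_book)
    n = small_book.word_length
    corrupted = dna[:n] + "CGCG" + dna[2 * n :]  # CG is forbidden, so not a code word
    with pytest.raises(DecodeError) as err:
        decode(corrupted, small_book)
    assert err.value.offset == n


def test_unaddressable_index_is_corruption():
    book = Codebook(1, ["A", "C", "G"])  # b = 1: only A and C addressable
    with pytest.raises(CorruptionError):
        decode("AG", book, with_header=False)


def test_truncation_errors(small_book):
    dna = encode(bytes(100), small_book)
    n = small_book.word_length
    with pytest.raises(TruncationError):
        decode(dna[: 10 * n], small_book)  # header says 800 bits, far fewer present
    with pytest.raises(TruncationError):
        decode("", small_book)


def test_realized_rate_formula(benchmark_codebook):
    """Block count and rate from first principles: a 2250-byte payload plus
    the 64-bit header fills ceil((64 + 18000) / 18) = 1004 words."""
    b = block_size(len(benchmark_codebook))
    assert b == 18
    payload = bytes(2250)
    dna = encode(payload, benchmark_codebook)
    expected_words = math.ceil((HEADER_BITS + 8 * 2250) / b)
    assert expected_words == 1004
    assert len(dna) == expected_words * 10
    assert realized_rate(payload, dna) == pytest.approx(18000 / 10040)


def test_rate_bounded_by_block_rate(small_book):
    b = block_size(len(small_book))
    n = small_book.word_length
    for size in (1, 50, 1000):
        payload = bytes(size)
        rate = realized_rate(payload, encode(payload, small_book))
        assert rate <= b / n + 1e-12


def test_rate_edge_cases(small_book):
    dna = encode(b"", small_book)
    assert realized_rate(b"", dna) == 0.0
    with pytest.raises(ParameterError):
        realized_rate(b"x", "")
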