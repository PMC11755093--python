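import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from poretrellis import (
    CodeParams,
    MessageRecord,
    StrandLayout,
    encode,
    encode_payload_region,
    hash_rank,
    next_base,
    payload_length,
    reverse_complement,
)
from poretrellis.hedges_code import (
    _digest,
    _digest_batch,
    _next_base_batch,
    bits_to_bytes,
    bytes_to_bits,
    crc8,
    encode_bits,
    seq_to_codes,
)

RATES = ["1/8", "1/6", "1/3", "1/2"]


def _splitmix64_reference(x: int) -> int:
    """Independent scripted reimplementation of the avalanche mix."""
    m = (1 << 64) - 1
    x = (x + 0x9E3779B97F4A7C15) & m
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & m
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & m
    return (x ^ (x >> 31)) & m


class TestHashRank:
    def test_deterministic(self):
        assert hash_rank(3, 9, 1, 42) == hash_rank(3, 9, 1, 42)

    def test_golden_values(self):
        # pinned after first implementation; never change
        assert hash_rank(0, 0, 0, 0) == (2, 3, 0, 1)
        assert hash_rank(5, 17, 1, 42) == (0, 3, 1, 2)

    def test_matches_independent_reimplementation(self):
        perms = sorted(itertools.permutations(range(4)))
        for h, j, b, salt in [(0, 0, 0, 0), (7, 3, 1, 5), (255, 100, 0, 99)]:
            d = _splitmix64_reference(salt)
            d = _splitmix64_reference(d ^ h)
            d = _splitmix64_reference(d ^ j)
            d = _splitmix64_reference(d ^ b)
            assert hash_rank(h, j, b, salt) == perms[d % 24]

    def test_first_symbol_uniform_over_histories(self):
        # exhaustive enumeration over all 2^8 histories
        counts = [0, 0, 0, 0]
        for h in range(256):
            counts[hash_rank(h, 11, 0, 3)[0]] += 1
        assert chisquare(counts).pvalue > 0.001

    def test_batch_digest_matches_scalar(self):
        hs = np.arange(64, dtype=np.uint64)
        batch = _digest_batch(hs, 13, 1, 99)
        for h in range(64):
            assert int(batch[h]) == _digest(h, 13, 1, 99)


class TestNextBase:
    def test_homopolymer_mask(self, params):
        # after a max-length run the same base is never emitted
        for h in range(16):
            for j in range(20):
                b = next_base(h, j, 0, "AAA", params)
                assert b != "A"

    def test_max_homopolymer_one(self):
        p = CodeParams(rate_id="1/2", history_bits=4, max_homopolymer=1)
        seq = encode_bits([0, 1] * 24, p)
        assert all(a != b for a, b in zip(seq, seq[1:]))

    def test_gc_window_within_tolerance(self, params, layout):
        rng = np.random.default_rng(0)
        for _ in range(20):
            payload = rng.integers(0, 256, 24, dtype=np.uint8).tobytes()
            rec = MessageRecord.build(0, payload, params.index_bytes)
            seq = encode_payload_region(rec, params, layout)
            w = params.gc_window
            for i in range(len(seq) - w + 1):
                win = seq[i : i + w]
                gc = sum(c in "GC" for c in win) / w
                assert abs(gc - params.gc_target) <= params.gc_tolerance + 1e-12

    def test_pure_function(self, params):
        a = next_base(5, 3, 1, "ACGTACGTACG", params)
        b = next_base(5, 3, 1, "ACGTACGTACG", params)
        assert a == b

    def test_batch_matches_scalar(self, params):
        rng = np.random.default_rng(3)
        W = params.recent_window
        for j in (0, 5, 17):
            recent = rng.integers(0, 4, size=(16, W)).astype(np.uint8)
            # avoid degenerate all-equal windows being the only case
            for bit in (0, 1):
                batch = _next_base_batch(
                    np.arange(16, dtype=np.uint64), j, bit, recent, params)
                for h in range(16):
                    rec_str = "".join(params.alphabet[c] for c in recent[h])
                    assert params.alphabet[batch[h]] == next_base(
                        h, j, bit, rec_str, params)


class TestEncode:
    def test_rate_arithmetic(self):
        p = CodeParams(rate_id="1/2", history_bits=4)
        seq = encode_bits([1, 0, 1, 1, 0, 0, 1, 0], p)
        assert len(seq) == 16

    @pytest.mark.parametrize("rate", RATES)
    def test_payload_length_matches_rate(self, rate):
        p = CodeParams(rate_id=rate, history_bits=4)
        n_bits = p.total_bits(8)
        assert payload_length(p, 8) == n_bits * p.period
        # information bits / payload bases == rate exactly
        assert n_bits / payload_length(p, 8) == pytest.approx(p.rate)

    def test_deterministic(self, params, layout):
        rec = MessageRecord.build(1, b"abcdef", params.index_bytes)
        assert encode(rec, params, layout) == encode(rec, params, layout)

    def test_layout_invariants(self, params, layout):
        rec = MessageRecord.build(1, b"abcdef", params.index_bytes)
        strand = encode(rec, params, layout)
        plen = payload_length(params, 6)
        assert len(strand) == 19 + 8 + 50 + plen + 50 + 10
        lo, hi = layout.payload_span(plen)
        assert strand[:lo] == layout.prefix
        assert strand[hi:] == layout.suffix

    def test_single_bit_divergence(self, layout):
        # convolutional context: a bit flip decorrelates the base sequence
        # for as long as the flipped bit sits in the H-bit history register
        # (a sliding-window history reconverges after H further bit steps,
        # so the decorrelation claim applies to the influenced window)
        p = CodeParams(rate_id="1/2", history_bits=8, salt=3)
        rng = np.random.default_rng(42)
        dists = []
        for _ in range(100):
            bits = rng.integers(0, 2, 64).tolist()
            flipped = list(bits)
            flip_at = int(rng.integers(0, 8))
            flipped[flip_at] ^= 1
            a = encode_bits(bits, p, layout.recent_seed(p))
            b = encode_bits(flipped, p, layout.recent_seed(p))
            start = flip_at * p.period
            end = (flip_at + p.history_bits + 1) * p.period
            wa, wb = a[start:end], b[start:end]
            d = sum(x != y for x, y in zip(wa, wb)) / len(wa)
            dists.append(d)
        assert np.mean(dists) > 0.40

    def test_homopolymer_scan_random_strands(self, layout):
        rng = np.random.default_rng(7)
        for i in range(1000):
            rate = RATES[i % 4]
            p = CodeParams(rate_id=rate, history_bits=4, salt=int(rng.integers(1000)))
            payload = rng.integers(0, 256, 4, dtype=np.uint8).tobytes()
            rec = MessageRecord.build(i % 100, payload, p.index_bytes)
            seq = encode_payload_region(rec, p, layout)
            run, longest, prev = 0, 0, ""
            for c in seq:
                run = run + 1 if c == prev else 1
                prev = c
                longest = max(longest, run)
            assert longest <= p.max_homopolymer

    def test_payload_too_long(self, params, layout):
        p = CodeParams(rate_id="1/2", max_payload_bytes=4)
        rec = MessageRecord.build(0, b"12345", p.index_bytes)
        with pytest.raises(ValueError, match="payload too long"):
            encode(rec, p, layout)


class TestMessageRecord:
    def test_crc_roundtrip(self):
        rec = MessageRecord.build(3, b"xyz", 2)
        assert rec.crc_ok
        back = MessageRecord.from_bits(rec.to_bits(), 2)
        assert back == rec
        assert back.index == 3

    def test_crc_detects_flip(self):
        rec = MessageRecord.build(3, b"xyz", 2)
        bad = MessageRecord(b"\x00\x04", rec.crc_byte, rec.payload_bytes)
        assert not bad.crc_ok

    def test_serialization_order(self):
        rec = MessageRecord.build(0x0102, b"\xAB", 2)
        assert rec.to_bytes() == b"\x01\x02" + bytes([crc8(b"\x01\x02")]) + b"\xAB"

    @given(st.binary(min_size=0, max_size=32))
    @settings(max_examples=50, deadline=None)
    def test_bits_bytes_roundtrip(self, data):
        assert bits_to_bytes(bytes_to_bits(data)) == data


class TestReverseComplement:
    def test_palindrome(self):
        assert reverse_complement("ACGT") == "ACGT"

    def test_by_definition(self):
        assert reverse_complement("AAAC") == "GTTT"

    def test_rna(self):
        assert reverse_complement("ACGU", ("A", "C", "G", "U")) == "ACGU"
        assert reverse_complement("AAU", ("A", "C", "G", "U")) == "AUU"

    @given(st.text(alphabet="ACGT", min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_invalid_symbol(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGX")


class TestCodeParams:
    @pytest.mark.parametrize("rate", RATES)
    def test_bit_pattern_mean_equals_rate(self, rate):
        p = CodeParams(rate_id=rate)
        assert sum(p.bit_pattern) / len(p.bit_pattern) == p.rate

    def test_invalid(self):
        with pytest.raises(ValueError):
            CodeParams(rate_id="2/3")
        with pytest.raises(ValueError):
            CodeParams(max_homopolymer=0)
        with pytest.raises(ValueError):
            CodeParams(gc_target=1.5)

    def test_dict_roundtrip(self, params):
        assert CodeParams.from_dict(params.to_dict()) == params
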