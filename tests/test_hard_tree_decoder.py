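import itertools

import numpy as np
import pytest

from poretrellis import (
    CodeParams,
    MessageRecord,
    StrandLayout,
    encode,
    encode_payload_region,
    reverse_complement,
)
from poretrellis.hard_tree_decoder import (
    EditCosts,
    decode_hard,
    decode_read,
    demultiplex,
)


@pytest.fixture
def setup(layout):
    p = CodeParams(rate_id="1/2", history_bits=4, salt=7)
    payload = b"hard!"
    rec = MessageRecord.build(3, payload, p.index_bytes)
    seq = encode_payload_region(rec, p, layout)
    return p, payload, rec, seq


def _mutate(seq: str, n_sub: int, rng) -> str:
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_sub, replace=False):
        out[pos] = rng.choice([c for c in "ACGT" if c != seq[pos]])
    return "".join(out)


class TestDecodeHard:
    def test_error_free_exact_zero_penalty(self, layout, setup):
        p, payload, rec, seq = setup
        res = decode_hard(seq, p, layout, len(payload), guess_limit=100_000)
        assert res.ok and res.crc_ok
        assert res.payload == payload
        assert res.index == 3
        assert res.score == 0.0

    def test_single_substitution_recovered(self, layout, setup):
        p, payload, rec, seq = setup
        rng = np.random.default_rng(11)
        good = 0
        for _ in range(100):
            read = _mutate(seq, 1, rng)
            res = decode_hard(read, p, layout, len(payload), guess_limit=10_000)
            good += res.ok and res.payload == payload
        assert good >= 99

    def test_single_indel_recovered(self, layout, setup):
        p, payload, rec, seq = setup
        # deletion
        read = seq[:30] + seq[31:]
        res = decode_hard(read, p, layout, len(payload), guess_limit=50_000)
        assert res.ok and res.payload == payload
        # insertion
        read = seq[:30] + "G" + seq[30:]
        res = decode_hard(read, p, layout, len(payload), guess_limit=50_000)
        assert res.ok and res.payload == payload

    def test_budget_respected_and_failure_flag(self, layout, setup):
        p, payload, rec, seq = setup
        rng = np.random.default_rng(0)
        soup = "".join(rng.choice(list("ACGT"), len(seq)))
        res = decode_hard(soup, p, layout, len(payload), guess_limit=500)
        assert res.guesses_used <= 500
        if res.ok:
            assert res.payload is not None

    def test_error_rate_monotone_in_noise(self, layout):
        # short code so the mid noise level is partially decodable and the
        # byte error rate can resolve a strict ordering over {1%, 5%, 10%}
        p = CodeParams(rate_id="1/2", history_bits=4, salt=7, index_bytes=1)
        payload = b"mono"
        rec = MessageRecord.build(2, payload, 1)
        seq = encode_payload_region(rec, p, layout)
        rng = np.random.default_rng(5)
        rates = []
        for frac in (0.01, 0.05, 0.10):
            n_err = max(1, round(frac * len(seq)))
            byte_errs = 0
            for _ in range(40):
                read = _mutate(seq, n_err, rng)
                res = decode_hard(read, p, layout, len(payload),
                                  guess_limit=10_000)
                if res.ok and res.payload is not None:
                    byte_errs += sum(a != b for a, b in
                                     zip(res.payload, payload))
                else:
                    byte_errs += len(payload)
            rates.append(byte_errs / (40 * len(payload)))
        assert rates[0] < rates[1] < rates[2]

    def test_budget_monotone_success(self, layout, setup):
        p, payload, rec, seq = setup
        rng = np.random.default_rng(21)
        reads = [_mutate(seq, 3, rng) for _ in range(30)]
        succ = []
        for limit in (200, 2_000, 20_000):
            ok = sum(decode_hard(r, p, layout, len(payload), limit).payload
                     == payload for r in reads)
            succ.append(ok)
        assert succ[0] <= succ[1] <= succ[2]

    def test_empty_input(self, layout, setup):
        p, payload, rec, seq = setup
        res = decode_hard("", p, layout, len(payload))
        assert not res.ok


def _all_codewords(p, layout, n_bits):
    """Every bit hypothesis of the code, encoded, as an (2^n_bits, L) array.

    Vectorised mirror of the encoder over all bit strings at once; this is
    the decoder's full hypothesis space (CRC validity is checked later by
    the caller of the decoder, not by the search itself).
    """
    from poretrellis.hedges_code import _next_base_batch

    n_words = 1 << n_bits
    bits = ((np.arange(n_words)[:, None] >> np.arange(n_bits - 1, -1, -1))
            & 1).astype(np.uint8)
    W = p.recent_window
    seed = np.frombuffer(layout.recent_seed(p), dtype=np.uint8)
    recent = np.tile(seed, (n_words, 1))
    history = np.zeros(n_words, dtype=np.uint64)
    L = n_bits * p.period
    out = np.zeros((n_words, L), dtype=np.uint8)
    consumed = 0
    for j in range(L):
        if p.is_bit_step(j):
            b = bits[:, consumed]
            consumed += 1
        else:
            b = np.zeros(n_words, dtype=np.uint8)
        c0 = _next_base_batch(history, j, 0, recent, p)
        c1 = _next_base_batch(history, j, 1, recent, p)
        code = np.where(b == 0, c0, c1)
        out[:, j] = code
        recent = np.concatenate([recent[:, 1:], code[:, None]], axis=1)
        if p.is_bit_step(j):
            history = ((history << np.uint64(1)) | b.astype(np.uint64)) \
                & np.uint64(p.history_mask)
    return out


def _levenshtein_to_all(read_codes: np.ndarray, words: np.ndarray) -> int:
    """Min unit-cost Levenshtein distance from the read to any codeword,
    dynamic programme vectorised across all words."""
    n_words, L = words.shape
    m = len(read_codes)
    dp = np.tile(np.arange(L + 1, dtype=np.int32), (n_words, 1))
    for i in range(1, m + 1):
        prev = dp
        dp = np.empty_like(prev)
        dp[:, 0] = i
        sub = prev[:, :-1] + (words != read_codes[i - 1])
        ins = prev[:, 1:] + 1
        dp[:, 1:] = np.minimum(sub, ins)
        # deletion needs a sequential pass along j
        for j in range(1, L + 1):
            np.minimum(dp[:, j], dp[:, j - 1] + 1, out=dp[:, j])
    return int(dp[:, -1].min())


class TestBestFirstOptimality:
    def test_minimal_penalty_vs_exhaustive(self, layout):
        """Best-first penalty equals the exhaustive minimum edit distance
        from the read to ANY bit hypothesis of a tiny code."""
        p = CodeParams(rate_id="1/2", history_bits=2, salt=1, index_bytes=1)
        n_payload = 0  # header-only message: 16 bits -> 32 bases
        n_bits = p.total_bits(n_payload)
        words = _all_codewords(p, layout, n_bits)
        from poretrellis.hedges_code import seq_to_codes

        rng = np.random.default_rng(3)
        for trial in range(6):
            idx = int(rng.integers(0, 256))
            rec = MessageRecord.build(idx, b"", 1)
            seq = encode_payload_region(rec, p, layout)
            read = _mutate(seq, 2, rng)
            res = decode_hard(read, p, layout, n_payload, guess_limit=2_000_000)
            assert res.ok
            best = _levenshtein_to_all(
                np.frombuffer(seq_to_codes(read), dtype=np.uint8), words)
            assert -res.score == pytest.approx(best)


class TestDemultiplex:
    def test_clean_read_attributed(self, layout):
        p = CodeParams(rate_id="1/2", history_bits=4, salt=7)
        rec = MessageRecord.build(3, b"abcd", p.index_bytes)
        strand = encode(rec, p, layout)
        assert demultiplex(strand, p, layout, 4, guess_limit=20_000) == 3

    def test_reverse_complement_attributed(self, layout):
        p = CodeParams(rate_id="1/2", history_bits=4, salt=7)
        rec = MessageRecord.build(3, b"abcd", p.index_bytes)
        strand = encode(rec, p, layout)
        rc = reverse_complement(strand)
        assert demultiplex(rc, p, layout, 4, guess_limit=20_000) == 3

    def test_random_soup_rejected(self, layout):
        p = CodeParams(rate_id="1/2", history_bits=4, salt=7)
        rec = MessageRecord.build(0, b"abcd", p.index_bytes)
        full_len = len(encode(rec, p, layout))
        rng = np.random.default_rng(13)
        rejected = 0
        n = 200
        for _ in range(n):
            soup = "".join(rng.choice(list("ACGT"), full_len))
            if demultiplex(soup, p, layout, 4, guess_limit=2_000) is None:
                rejected += 1
        assert rejected >= 0.97 * n

    def test_decode_read_orientation_stat(self, layout):
        p = CodeParams(rate_id="1/2", history_bits=4, salt=7)
        rec = MessageRecord.build(5, b"or", p.index_bytes)
        strand = encode(rec, p, layout)
        res = decode_read(strand, p, layout, 2, guess_limit=20_000)
        assert res.stats["orientation"] == "forward"
        res_rc = decode_read(reverse_complement(strand), p, layout, 2,
                             guess_limit=20_000)
        assert res_rc.stats["orientation"] == "reverse_complement"
        assert res_rc.payload == b"or"
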