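"""Alignment-matrix trellis soft decoder.

A 2^H-state trellis is walked over message base steps; each state stores a
single row of CTC forward variables for its surviving message prefix.  An
edge extends the predecessor's row by one emitted base with a dynamic
programming recurrence (one interleaved blank row plus one base row, both
derived solely from the previous base row) and is scored by the
log-sum-exp of the fresh row.  Per state the best-scoring incoming edge
survives, so live memory stays at O(2^H * T) forward variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels
from .ctc_sim import CTCMatrix
from .hard_tree_decoder import DecodeResult, _bits_to_result
from .hedges_code import (
    CodeParams,
    StrandLayout,
    _next_base_batch,
    codes_to_seq,
    seq_to_codes,
)

__all__ = ["PrefixRow", "AMState", "init_row", "extend_row",
           "decode_soft_am", "per_byte_error_profile"]


@dataclass
class PrefixRow:
    """One row of forward variables M(i, t) for a message prefix.

    ``values[t]`` is the log of the summed probability of all CTC-encodings
    of the prefix that end at time t on the prefix's last base.
    """

    values: np.ndarray
    prefix_len: int
    last_base: Optional[int] = None


@dataclass
class AMState:
    history: int
    row: PrefixRow
    score: float
    traceback: list


def init_row(ctc: CTCMatrix) -> PrefixRow:
    """Empty-prefix base case: cumulative all-blank path probabilities."""
    return PrefixRow(np.cumsum(ctc.logp[:, 0]), 0, None)


def extend_row(prev: PrefixRow, new_base: int | str,
               ctc: CTCMatrix) -> tuple[PrefixRow, PrefixRow]:
    """Extend a prefix row by one base.

    Returns ``(blank_row, base_row)``: the interleaved blank row (the
    trailing-blank row of the previous prefix) and the new base's row.
    When ``new_base`` equals the previous last base, the direct skip term
    is dropped so at least one blank separates the repeat.
    """
    if isinstance(new_base, str):
        new_base = ctc.alphabet.index(new_base)
    T = ctc.T
    lp = np.ascontiguousarray(ctc.logp)
    Q = np.empty(T)
    R = np.empty(T)
    same = prev.last_base is not None and new_base == prev.last_base
    _kernels.extend_one(np.ascontiguousarray(prev.values, dtype=np.float64),
                        lp[:, 0].copy(), lp[:, new_base + 1].copy(),
                        same, prev.prefix_len == 0, Q, R)
    blank_row = PrefixRow(Q, prev.prefix_len, prev.last_base)
    base_row = PrefixRow(R, prev.prefix_len + 1, new_base)
    return blank_row, base_row


def decode_soft_am(ctc: CTCMatrix, params: CodeParams, layout: StrandLayout,
                   n_payload_bytes: int) -> DecodeResult:
    """Run the full trellis over a payload-region CTC matrix.

    Time scales as O(2^H * L * T); live forward-variable storage is two
    (2^H, T) row banks plus a (2, T) per-edge scratch.
    """
    T = ctc.T
    lp = np.ascontiguousarray(ctc.logp)
    n_bits = params.total_bits(n_payload_bytes)
    L = n_bits * params.period
    if T < 1 or L < 1:
        return DecodeResult(ok=False)
    S = params.n_states
    W = params.recent_window
    hi_bit = 1 << (params.history_bits - 1)

    rows = np.full((S, T), -np.inf)
    rows[0] = np.cumsum(lp[:, 0])
    rows_next = np.full((S, T), -np.inf)
    alive = np.zeros(S, dtype=np.bool_)
    alive[0] = True
    score = np.full(S, -np.inf)
    last_base = np.full(S, 255, dtype=np.uint8)
    seed = np.frombuffer(layout.recent_seed(params), dtype=np.uint8)
    recent = np.tile(seed, (S, 1))

    tb_pred = np.zeros((L, S), dtype=np.int32)
    tb_bit = np.full((L, S), -1, dtype=np.int8)
    tb_base = np.zeros((L, S), dtype=np.uint8)

    all_states = np.arange(S, dtype=np.uint64)
    preds = np.zeros((S, 2), dtype=np.int64)
    bases = np.zeros((S, 2), dtype=np.uint8)
    bits_arr = np.zeros((S, 2), dtype=np.int8)
    nedge = np.zeros(S, dtype=np.int64)
    same = np.zeros((S, 2), dtype=np.bool_)
    out_score = np.empty(S)
    out_edge = np.empty(S, dtype=np.int64)
    scratch = np.empty((2, T))
    sidx = np.arange(S)

    # allocation accounting for the memory contract: persistent row banks
    peak_row_values = rows.size + rows_next.size
    scratch_values = scratch.size

    for j in range(L):
        bit_step = params.is_bit_step(j)
        if bit_step:
            b0 = _next_base_batch(all_states, j, 0, recent, params)
            b1 = _next_base_batch(all_states, j, 1, recent, params)
            bit_of = sidx & 1
            p0 = sidx >> 1
            p1 = (sidx >> 1) | hi_bit
            e0 = np.where(bit_of == 0, b0[p0], b1[p0])
            e1 = np.where(bit_of == 0, b0[p1], b1[p1])
            # deterministic tie-break: same bit on both edges, so order
            # edges by (emitted base, predecessor index)
            swap = (e1 < e0)
            preds[:, 0] = np.where(swap, p1, p0)
            preds[:, 1] = np.where(swap, p0, p1)
            bases[:, 0] = np.where(swap, e1, e0)
            bases[:, 1] = np.where(swap, e0, e1)
            bits_arr[:, 0] = bit_of
            bits_arr[:, 1] = bit_of
            nedge[:] = 2
        else:
            b0 = _next_base_batch(all_states, j, 0, recent, params)
            preds[:, 0] = sidx
            bases[:, 0] = b0
            bits_arr[:, 0] = -1
            nedge[:] = 1
        same[:, 0] = bases[:, 0] == last_base[preds[:, 0]]
        same[:, 1] = bases[:, 1] == last_base[preds[:, 1]]

        _kernels.am_step(rows, alive, lp, bases, preds, nedge, same,
                         j == 0, rows_next, out_score, out_edge, scratch)

        chosen = np.maximum(out_edge, 0)
        cp = preds[sidx, chosen]
        cb = bases[sidx, chosen]
        tb_pred[j] = cp
        tb_bit[j] = bits_arr[sidx, chosen]
        tb_base[j] = cb
        alive = (out_edge >= 0) & np.isfinite(out_score)
        score = np.where(alive, out_score, -np.inf)
        last_base = np.where(alive, cb, np.uint8(255)).astype(np.uint8)
        recent = np.concatenate([recent[cp][:, 1:], cb[:, None]], axis=1)
        rows, rows_next = rows_next, rows

    if not alive.any():
        return DecodeResult(ok=False, stats={"peak_row_values": peak_row_values,
                                             "scratch_values": scratch_values})
    s = int(np.argmax(np.where(alive, score, -np.inf)))
    final_score = float(score[s])
    bits: list[int] = []
    msg_codes: list[int] = []
    cur = s
    for j in range(L - 1, -1, -1):
        msg_codes.append(int(tb_base[j, cur]))
        if tb_bit[j, cur] >= 0:
            bits.append(int(tb_bit[j, cur]))
        cur = int(tb_pred[j, cur])
    bits.reverse()
    msg_codes.reverse()
    message = codes_to_seq(msg_codes, params.alphabet)
    res = _bits_to_result(bits, params, message, final_score, 0)
    res.stats["peak_row_values"] = peak_row_values
    res.stats["scratch_values"] = scratch_values
    res.stats["n_states"] = S
    res.stats["T"] = T
    return res


def per_byte_error_profile(decoded: list[Optional[bytes]],
                           truth: list[bytes]) -> dict:
    """Per-byte-position error frequencies with Wilson 95% intervals.

    A failed decode (``None``) counts as an error at every position.
    Returns ``profile``, the mean rate ``p_bar`` and the interval bounds.
    """
    if not decoded:
        raise ValueError("need at least one decoded read")
    if len(decoded) != len(truth):
        raise ValueError("decoded/truth length mismatch")
    n_pos = len(truth[0])
    errors = np.zeros(n_pos, dtype=np.int64)
    for dec, tru in zip(decoded, truth):
        if dec is None or len(dec) != len(tru):
            errors += 1
        else:
            errors += np.frombuffer(dec, np.uint8) != np.frombuffer(tru, np.uint8)
    n = len(decoded)
    profile = errors / n
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(errors, n, alpha=0.05, method="wilson")
    return {
        "profile": profile,
        "p_bar": float(profile.mean()),
        "wilson_low": np.asarray(lo, dtype=float),
        "wilson_high": np.asarray(hi, dtype=float),
        "n_reads": n,
    }
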