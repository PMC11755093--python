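"""Beam-trellis soft decoder (accuracy baseline).

States are (history, message index) slots updated once per CTC time step.
Every state carries a blank and a non-blank score half; candidates that
convey the same message are merged by log-sum-exp, distinct messages
colliding in a slot are resolved by keeping the higher total score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .ctc_sim import CTCMatrix
from .hard_tree_decoder import DecodeResult, _bits_to_result
from .hedges_code import (
    CodeParams,
    StrandLayout,
    _next_base_code,
    codes_to_seq,
)

__all__ = ["BeamState", "BeamTrellis", "beam_step", "merge_duplicates",
           "decode_soft_beam", "total_score"]

_NEG_INF = -np.inf

# 64-bit rolling hash (polynomial, odd multiplier); quick message-equality
# filter — candidates with equal hashes are confirmed by a full comparison
_HASH_MUL = 0x100000001B3
_M64 = (1 << 64) - 1


def _roll(h: int, code: int) -> int:
    return ((h * _HASH_MUL) ^ (code + 1)) & _M64


def _ladd(a: float, b: float) -> float:
    if a == _NEG_INF:
        return b
    if b == _NEG_INF:
        return a
    if a < b:
        a, b = b, a
    return a + math.log1p(math.exp(b - a))


def total_score(score_blank: float, score_nonblank: float) -> float:
    return _ladd(score_blank, score_nonblank)


@dataclass(slots=True)
class BeamState:
    """One trellis slot survivor: (history, message index, message, scores)."""

    history: int
    msg_index: int
    message: bytes  # emitted base codes so far
    score_blank: float
    score_nonblank: float
    bits: bytes = b""
    msg_hash: int = 0

    @property
    def total(self) -> float:
        return total_score(self.score_blank, self.score_nonblank)


def merge_duplicates(states: list[BeamState]) -> list[BeamState]:
    """Merge states per (history, msg_index) slot.

    Identical messages have their blank/non-blank scores log-sum-exp
    combined; distinct messages in one slot keep only the highest-total
    survivor.  Idempotent.
    """
    slots: dict[tuple[int, int], BeamState] = {}
    for st in states:
        key = (st.history, st.msg_index)
        cur = slots.get(key)
        if cur is None:
            slots[key] = BeamState(st.history, st.msg_index, st.message,
                                   st.score_blank, st.score_nonblank,
                                   st.bits, st.msg_hash)
        elif (cur.msg_hash == st.msg_hash and cur.message == st.message):
            cur.score_blank = _ladd(cur.score_blank, st.score_blank)
            cur.score_nonblank = _ladd(cur.score_nonblank, st.score_nonblank)
        elif st.total > cur.total:
            slots[key] = BeamState(st.history, st.msg_index, st.message,
                                   st.score_blank, st.score_nonblank,
                                   st.bits, st.msg_hash)
    return list(slots.values())


class BeamTrellis:
    """Shared context for stepping beam states over a CTC matrix."""

    def __init__(self, params: CodeParams, layout: StrandLayout, L: int,
                 prune_margin: Optional[float] = 300.0):
        self.params = params
        self.layout = layout
        self.L = L
        self.prune_margin = prune_margin
        self._seed = layout.recent_seed(params)
        self._base_cache: dict = {}

    def initial_states(self) -> list[BeamState]:
        return [BeamState(history=0, msg_index=0, message=b"",
                          score_blank=0.0, score_nonblank=_NEG_INF)]

    def _emit(self, history: int, msg_index: int, bit: int,
              message: bytes) -> int:
        W = self.params.recent_window
        recent = (self._seed + message)[-W:]
        key = (history, msg_index, bit, recent)
        code = self._base_cache.get(key)
        if code is None:
            code = _next_base_code(history, msg_index, bit, recent, self.params)
            self._base_cache[key] = code
        return code

    def step(self, states: list[BeamState], column: np.ndarray) -> list[BeamState]:
        """Advance all states across one CTC time step.

        Three candidates per state: the stay candidate keeps the message
        and accrues blank (or repeated last base) probability; the advance
        candidates append one emitted base per bit guess, drawing only from
        the blank half when the base repeats.
        """
        params = self.params
        col = [float(v) for v in column]
        lb = col[0]
        # inline merge (same semantics as merge_duplicates): equal-message
        # candidates sum score halves, distinct ones keep the higher total
        slots: dict[tuple[int, int], BeamState] = {}

        def push(h, i, msg, pb, pnb, bits, mhash):
            key = (h, i)
            cur = slots.get(key)
            if cur is None:
                slots[key] = BeamState(h, i, msg, pb, pnb, bits, mhash)
            elif cur.msg_hash == mhash and cur.message == msg:
                cur.score_blank = _ladd(cur.score_blank, pb)
                cur.score_nonblank = _ladd(cur.score_nonblank, pnb)
            elif _ladd(pb, pnb) > cur.total:
                slots[key] = BeamState(h, i, msg, pb, pnb, bits, mhash)

        for st in states:
            tot = st.total
            msg = st.message
            # stay candidate S_W
            pnb = (st.score_nonblank + col[msg[-1] + 1] if msg else _NEG_INF)
            push(st.history, st.msg_index, msg, lb + tot, pnb,
                 st.bits, st.msg_hash)
            # advance candidates S_X, S_Y
            if st.msg_index < self.L:
                bit_step = params.is_bit_step(st.msg_index)
                for bit in ((0, 1) if bit_step else (0,)):
                    code = self._emit(st.history, st.msg_index, bit, msg)
                    lc = col[code + 1]
                    if msg and msg[-1] == code:
                        contrib = st.score_blank + lc
                    else:
                        contrib = tot + lc
                    if contrib == _NEG_INF:
                        continue
                    h2 = (((st.history << 1) | bit) & params.history_mask
                          if bit_step else st.history)
                    bits2 = st.bits + bytes([bit]) if bit_step else st.bits
                    push(h2, st.msg_index + 1, msg + bytes([code]),
                         _NEG_INF, contrib, bits2, _roll(st.msg_hash, code))
        merged = list(slots.values())
        if self.prune_margin is not None and merged:
            best = max(s.total for s in merged)
            cut = best - self.prune_margin
            merged = [s for s in merged if s.total >= cut]
        return merged


def beam_step(states: list[BeamState], column: np.ndarray,
              trellis: BeamTrellis) -> list[BeamState]:
    """Functional wrapper around :meth:`BeamTrellis.step`."""
    return trellis.step(states, column)


def decode_soft_beam(ctc: CTCMatrix, params: CodeParams, layout: StrandLayout,
                     n_payload_bytes: int,
                     prune_margin: Optional[float] = 300.0) -> DecodeResult:
    """Run the beam trellis over a payload-region CTC matrix.

    ``prune_margin`` drops slots more than that many nats below the running
    best total; 300 nats is far beyond double precision resolution, so the
    default is numerically lossless.  ``None`` disables pruning entirely
    (full 2^H * (L+1) slot sweep, as the complexity analysis assumes).
    """
    n_bits = params.total_bits(n_payload_bytes)
    L = n_bits * params.period
    trellis = BeamTrellis(params, layout, L, prune_margin)
    states = trellis.initial_states()
    max_states = 0
    for t in range(ctc.T):
        states = trellis.step(states, ctc.logp[t])
        max_states = max(max_states, len(states))
        if not states:
            break
    finals = [s for s in states if s.msg_index == L]
    if not finals:
        return DecodeResult(ok=False, stats={"max_states": max_states})
    best = max(finals, key=lambda s: s.total)
    message = codes_to_seq(best.message, params.alphabet)
    res = _bits_to_result(list(best.bits), params, message, best.total, 0)
    res.stats["max_states"] = max_states
    res.stats["slot_bound"] = params.n_states * (L + 1)
    return res
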