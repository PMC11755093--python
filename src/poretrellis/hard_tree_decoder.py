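"""Baseline hard decoder: best-first search over a tree of bit guesses.

Each node hypothesises one decoding step against the basecalled sequence,
considering match / substitution / insertion / deletion edits, and is
expanded in lowest-penalty-first order under a guess budget.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .hedges_code import (
    CodeParams,
    MessageRecord,
    StrandLayout,
    _next_base_code,
    bits_to_bytes,
    codes_to_seq,
    reverse_complement,
    seq_to_codes,
)

__all__ = ["EditCosts", "GuessNode", "DecodeResult", "decode_hard",
           "decode_read", "demultiplex", "locate_payload"]


@dataclass(frozen=True)
class EditCosts:
    match: float = 0.0
    substitution: float = 1.0
    insertion: float = 1.0
    deletion: float = 1.0


@dataclass
class GuessNode:
    """One node of the guess tree (exposed mainly for tests)."""

    parent: Optional["GuessNode"]
    bit: Optional[int]
    edit: str  # match | substitution | insertion | deletion | root
    seq_pos: int
    msg_pos: int
    history: int
    score: float
    base: Optional[int] = None
    recent: bytes = b""


@dataclass
class DecodeResult:
    """Outcome of any decoder (hard or soft)."""

    ok: bool
    message: Optional[str] = None
    payload: Optional[bytes] = None
    index: Optional[int] = None
    crc_ok: bool = False
    score: float = float("-inf")
    guesses_used: int = 0
    stats: dict = field(default_factory=dict)


def _bits_to_result(bits: Sequence[int], params: CodeParams, message: str,
                    score: float, guesses: int) -> DecodeResult:
    record = MessageRecord.from_bits(bits, params.index_bytes)
    return DecodeResult(
        ok=True,
        message=message,
        payload=record.payload_bytes,
        index=record.index,
        crc_ok=record.crc_ok,
        score=score,
        guesses_used=guesses,
    )


def decode_hard(basecalls: str, params: CodeParams, layout: StrandLayout,
                n_payload_bytes: int, guess_limit: int = 1_000_000,
                costs: EditCosts = EditCosts()) -> DecodeResult:
    """Best-first tree search over bit guesses against payload basecalls.

    ``basecalls`` must be the payload region only (fixed regions already
    trimmed; see :func:`decode_read` for full reads).  Returns the lowest
    penalty full-length hypothesis explored within ``guess_limit`` node
    expansions, or a failed result if the budget runs out first.
    """
    if not basecalls:
        return DecodeResult(ok=False, guesses_used=0)
    seq = seq_to_codes(basecalls, params.alphabet)
    n_seq = len(seq)
    n_bits = params.total_bits(n_payload_bytes)
    L = n_bits * params.period
    W = params.recent_window
    seed = layout.recent_seed(params)
    sub, ins, dele = costs.substitution, costs.insertion, costs.deletion

    # heap entries: (score, msg_pos tie-break, bit tie-break, counter, node)
    # node: (msg_pos, seq_pos, history, recent, parent, bit, is_goal)
    counter = 0
    root = (0, 0, 0, seed, None, None, False)
    heap: list = [(0.0, 0, 0, counter, root)]
    visited: dict = {}
    base_cache: dict = {}
    pops = 0

    while heap and pops < guess_limit:
        score, _, _, _, node = heapq.heappop(heap)
        msg_pos, seq_pos, history, recent, parent, bit, is_goal = node
        pops += 1
        if is_goal:
            bits = []
            cur = node
            while cur is not None:
                if cur[5] is not None:
                    bits.append(cur[5])
                cur = cur[4]
            bits.reverse()
            message = _reconstruct_message(bits, params, seed, L)
            return _bits_to_result(bits, params, message, -score, pops)

        key = (msg_pos, seq_pos, history, recent)
        prev = visited.get(key)
        if prev is not None and prev <= score:
            continue
        visited[key] = score

        bit_step = params.is_bit_step(msg_pos)
        options = (0, 1) if bit_step else (0,)
        for b in options:
            ck = (history, msg_pos, b, recent)
            code = base_cache.get(ck)
            if code is None:
                code = _next_base_code(history, msg_pos, b, recent, params)
                base_cache[ck] = code
            h2 = ((history << 1) | b) & params.history_mask if bit_step else history
            rec2 = (recent + bytes([code]))[-W:]
            nb = b if bit_step else None
            at_goal = msg_pos + 1 == L
            # match / substitution
            if seq_pos < n_seq:
                cost = costs.match if seq[seq_pos] == code else sub
                s2 = score + cost
                if at_goal:
                    s2 += ins * (n_seq - seq_pos - 1)
                counter += 1
                child = (msg_pos + 1, seq_pos + 1, h2, rec2, node, nb, at_goal)
                heapq.heappush(heap, (s2, msg_pos + 1, b, counter, child))
            # deletion: base emitted but absent from the read
            s2 = score + dele
            if at_goal:
                s2 += ins * (n_seq - seq_pos)
            counter += 1
            child = (msg_pos + 1, seq_pos, h2, rec2, node, nb, at_goal)
            heapq.heappush(heap, (s2, msg_pos + 1, b, counter, child))
        # insertion: extra read base, message does not advance
        if seq_pos < n_seq:
            counter += 1
            child = (msg_pos, seq_pos + 1, history, recent, node, None, False)
            heapq.heappush(heap, (score + ins, msg_pos, 0, counter, child))

    return DecodeResult(ok=False, guesses_used=pops)


def _reconstruct_message(bits: Sequence[int], params: CodeParams,
                         seed: bytes, L: int) -> str:
    recent = list(seed)
    history = 0
    out = []
    consumed = 0
    for j in range(L):
        if params.is_bit_step(j):
            b = bits[consumed]
            consumed += 1
        else:
            b = 0
        code = _next_base_code(history, j, b, recent, params)
        out.append(code)
        recent.append(code)
        if params.is_bit_step(j):
            history = ((history << 1) | b) & params.history_mask
    return codes_to_seq(out, params.alphabet)


def locate_payload(read: str, params: CodeParams, layout: StrandLayout,
                   n_payload_bytes: int) -> str:
    """Cut the payload region out of a full-strand read.

    Buffers are located by best approximate (Hamming) match; falls back to
    the nominal layout coordinates when the read is too short to search.
    """
    from .ctc_sim import _best_match  # shared sliding-window matcher

    codes = seq_to_codes(read, params.alphabet)
    lb = seq_to_codes(layout.left_buffer)
    rb = seq_to_codes(layout.right_buffer)
    pl, _ = _best_match(codes, lb)
    start = pl + len(lb)
    pr_rel, _ = _best_match(codes[start:], rb)
    end = start + pr_rel
    if end <= start:
        return ""
    return read[start:end]


def decode_read(read: str, params: CodeParams, layout: StrandLayout,
                n_payload_bytes: int, guess_limit: int = 1_000_000,
                costs: EditCosts = EditCosts(),
                try_reverse_complement: bool = True) -> DecodeResult:
    """Trim a full-strand read and hard-decode it, retrying on the RC."""
    payload = locate_payload(read, params, layout, n_payload_bytes)
    res = decode_hard(payload, params, layout, n_payload_bytes, guess_limit, costs)
    if res.ok and res.crc_ok:
        res.stats["orientation"] = "forward"
        return res
    if try_reverse_complement:
        rc = reverse_complement(read, params.alphabet)
        payload_rc = locate_payload(rc, params, layout, n_payload_bytes)
        res_rc = decode_hard(payload_rc, params, layout, n_payload_bytes,
                             guess_limit, costs)
        if res_rc.ok and res_rc.crc_ok:
            res_rc.stats["orientation"] = "reverse_complement"
            return res_rc
        if not res.ok or (res_rc.ok and res_rc.score > res.score):
            res_rc.stats["orientation"] = "reverse_complement"
            return res_rc
    res.stats["orientation"] = "forward"
    return res


def demultiplex(read: str, params: CodeParams, layout: StrandLayout,
                n_payload_bytes: int, guess_limit: int = 100_000) -> Optional[int]:
    """Attribute a read to a strand index iff the decoded CRC-8 validates."""
    res = decode_read(read, params, layout, n_payload_bytes, guess_limit)
    if res.ok and res.crc_ok:
        return res.index
    return None
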