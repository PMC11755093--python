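"""Constrained convolutional encoder for DNA/RNA data storage.

Each emitted base is chosen by hashing ``(salt, history bits, base index)``
into a ranking of the alphabet, hard-masking homopolymer violations,
reordering the survivors by a soft GC-window balancing preference, and
letting the encoded bit index the resulting order — so the two bit guesses
always emit distinct bases and error-free strands invert exactly.  The
history register makes the code convolutional: flipping one message bit
decorrelates the base sequence for as long as the bit stays in the
register, which is what the decoders exploit to reject wrong guesses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CodeParams",
    "StrandLayout",
    "MessageRecord",
    "hash_rank",
    "next_base",
    "encode",
    "encode_payload_region",
    "payload_length",
    "reverse_complement",
    "crc8",
    "bytes_to_bits",
    "bits_to_bytes",
    "DNA_ALPHABET",
    "RNA_ALPHABET",
]

DNA_ALPHABET = ("A", "C", "G", "T")
RNA_ALPHABET = ("A", "C", "G", "U")

# GC bases are at code positions 1 (C) and 2 (G) for both alphabets.
_GC_CODES = frozenset((1, 2))

_RATE_PATTERNS = {
    "1/8": (1, 0, 0, 0, 0, 0, 0, 0),
    "1/6": (1, 0, 0, 0, 0, 0),
    "1/3": (1, 0, 0),
    "1/2": (1, 0),
}

_M64 = (1 << 64) - 1
_PERMS = tuple(itertools.permutations(range(4)))
_PERMS_ARR = np.array(_PERMS, dtype=np.uint8)


# ---------------------------------------------------------------------------
# bit and checksum helpers
# ---------------------------------------------------------------------------

def bytes_to_bits(data: bytes) -> list[int]:
    """MSB-first bit expansion."""
    out = []
    for b in data:
        for i in range(7, -1, -1):
            out.append((b >> i) & 1)
    return out


def bits_to_bytes(bits: Sequence[int]) -> bytes:
    if len(bits) % 8:
        raise ValueError("bit count must be a multiple of 8")
    out = bytearray()
    for i in range(0, len(bits), 8):
        v = 0
        for b in bits[i : i + 8]:
            v = (v << 1) | (b & 1)
        out.append(v)
    return bytes(out)


def crc8(data: bytes, poly: int = 0x97, init: int = 0x00) -> int:
    """Bitwise CRC-8, MSB first."""
    crc = init
    for byte in data:
        crc ^= byte
        for _ in range(8):
            if crc & 0x80:
                crc = ((crc << 1) ^ poly) & 0xFF
            else:
                crc = (crc << 1) & 0xFF
    return crc


# ---------------------------------------------------------------------------
# integer hash
# ---------------------------------------------------------------------------

def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _M64
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _M64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _M64
    return (z ^ (z >> 31)) & _M64


def _digest(history: int, base_index: int, bit_guess: int, salt: int) -> int:
    h = _splitmix64(salt & _M64)
    h = _splitmix64(h ^ (history & _M64))
    h = _splitmix64(h ^ (base_index & _M64))
    h = _splitmix64(h ^ (bit_guess & 1))
    return h


def _digest_batch(
    histories: np.ndarray, base_index: int, bit_guess: int, salt: int
) -> np.ndarray:
    """Vectorised :func:`_digest` over an array of history values."""
    c1 = np.uint64(0x9E3779B97F4A7C15)
    c2 = np.uint64(0xBF58476D1CE4E5B9)
    c3 = np.uint64(0x94D049BB133111EB)

    def mix(x: np.ndarray) -> np.ndarray:
        x = x + c1
        x = (x ^ (x >> np.uint64(30))) * c2
        x = (x ^ (x >> np.uint64(27))) * c3
        return x ^ (x >> np.uint64(31))

    with np.errstate(over="ignore"):
        h = mix(np.full(histories.shape, salt & _M64, dtype=np.uint64))
        h = mix(h ^ histories.astype(np.uint64))
        h = mix(h ^ np.uint64(base_index & _M64))
        h = mix(h ^ np.uint64(bit_guess & 1))
    return h


def hash_rank(
    history: int, base_index: int, bit_guess: int, salt: int
) -> tuple[int, ...]:
    """Deterministic, salt-dependent ranking of the 4-symbol alphabet.

    Returns a permutation of ``(0, 1, 2, 3)``; index 0 is the preferred
    candidate.  Distinct argument triples give decorrelated permutations.
    """
    if history < 0 or base_index < 0:
        raise ValueError("history and base_index must be non-negative")
    return _PERMS[_digest(history, base_index, bit_guess, salt) % 24]


# ---------------------------------------------------------------------------
# parameters and layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodeParams:
    """All code parameters: rate, history width, constraints, header widths."""

    rate_id: str = "1/6"
    history_bits: int = 8
    salt: int = 0
    max_homopolymer: int = 3
    gc_window: int = 12
    gc_target: float = 0.5
    gc_tolerance: float = 0.25
    alphabet: tuple[str, ...] = DNA_ALPHABET
    index_bytes: int = 2
    max_payload_bytes: int = 4096

    def __post_init__(self) -> None:
        if self.rate_id not in _RATE_PATTERNS:
            raise ValueError(f"unsupported rate {self.rate_id!r}")
        if self.history_bits < 1:
            raise ValueError("history_bits must be >= 1")
        if self.max_homopolymer < 1:
            raise ValueError("max_homopolymer must be >= 1")
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError("gc_target must be in (0, 1)")
        if self.gc_window < 2:
            raise ValueError("gc_window must be >= 2")
        if len(self.alphabet) != 4:
            raise ValueError("alphabet must have 4 symbols")

    @property
    def bit_pattern(self) -> tuple[int, ...]:
        return _RATE_PATTERNS[self.rate_id]

    @property
    def period(self) -> int:
        return len(self.bit_pattern)

    @property
    def rate(self) -> float:
        return float(Fraction(self.rate_id))

    @property
    def n_states(self) -> int:
        return 1 << self.history_bits

    @property
    def history_mask(self) -> int:
        return (1 << self.history_bits) - 1

    @property
    def header_bytes(self) -> int:
        return self.index_bytes + 1  # index + CRC-8

    @property
    def recent_window(self) -> int:
        return max(self.gc_window - 1, self.max_homopolymer)

    def is_bit_step(self, base_index: int) -> bool:
        return self.bit_pattern[base_index % self.period] == 1

    def total_bits(self, n_payload_bytes: int) -> int:
        return (self.header_bytes + n_payload_bytes) * 8

    def to_dict(self) -> dict:
        return {
            "rate_id": self.rate_id,
            "history_bits": self.history_bits,
            "salt": self.salt,
            "max_homopolymer": self.max_homopolymer,
            "gc_window": self.gc_window,
            "gc_target": self.gc_target,
            "gc_tolerance": self.gc_tolerance,
            "alphabet": list(self.alphabet),
            "index_bytes": self.index_bytes,
            "max_payload_bytes": self.max_payload_bytes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CodeParams":
        d = dict(d)
        if "alphabet" in d:
            d["alphabet"] = tuple(d["alphabet"])
        return cls(**d)


def seq_to_codes(seq: str, alphabet: Sequence[str] = DNA_ALPHABET) -> bytes:
    lut = {s: i for i, s in enumerate(alphabet)}
    try:
        return bytes(lut[c] for c in seq)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"symbol {exc} not in alphabet {alphabet}") from exc


def codes_to_seq(codes: Iterable[int], alphabet: Sequence[str] = DNA_ALPHABET) -> str:
    return "".join(alphabet[c] for c in codes)


def _constrained_random_seq(length: int, tag: int, max_homopolymer: int = 3,
                            gc_window: int = 12, gc_target: float = 0.5,
                            gc_tolerance: float = 0.25) -> str:
    """Fixed pseudo-random sequence honouring the strand constraints.

    Used once to mint the buffer constants; keyed by ``tag`` so each fixed
    region gets its own stream.  Never change these streams: decoders and
    tests pin the resulting sequences.
    """
    out: list[int] = []
    for j in range(length):
        perm = _PERMS[_digest(0xB0FFE4, j, 0, tag) % 24]
        out.append(
            _pick_base(perm, out, 0, max_homopolymer, gc_window, gc_target,
                       gc_tolerance)
        )
    return codes_to_seq(out)


def _pick_base(perm: Sequence[int], recent: Sequence[int], bit: int,
               max_homopolymer: int, gc_window: int, gc_target: float,
               gc_tolerance: float) -> int:
    """Select the emitted base: constraint-mask, GC-order, then bit-index.

    Candidates in hash-rank order are hard-masked for homopolymers (at most
    one base removed, so >= 3 survive) and stably reordered so GC-tolerant
    choices come first (out-of-tolerance ones by ascending deviation).  The
    encoded bit indexes into this ordering, so bit 0 and bit 1 always emit
    DIFFERENT bases — the bit -> base map is injective given the state,
    which is what lets decoders invert error-free reads exactly.
    """
    n = len(recent)
    forbid = -1
    if n >= max_homopolymer:
        tail = recent[n - max_homopolymer :]
        if all(c == tail[0] for c in tail):
            forbid = tail[0]
    win = recent[max(0, n - (gc_window - 1)) :]
    g = sum(1 for c in win if c in _GC_CODES)
    wl = min(gc_window, n + 1)
    cands = [c for c in perm if c != forbid]
    keys = []
    for c in cands:
        dev = abs((g + (1 if c in _GC_CODES else 0)) / wl - gc_target)
        keys.append(0.0 if dev <= gc_tolerance + 1e-12 else 1.0 + dev)
    order = [c for _, c in sorted(zip(keys, cands), key=lambda t: t[0])]
    return order[bit % len(order)]


_T7_PROMOTER = "TAATACGACTCACTATAGG"  # 19 bp
_SYNTH_BUFFER = _constrained_random_seq(8, tag=11)
_LEFT_BUFFER = _constrained_random_seq(50, tag=12)
_RIGHT_BUFFER = _constrained_random_seq(50, tag=13)


@dataclass(frozen=True)
class StrandLayout:
    """Fixed regions flanking the information-carrying payload.

    Default full strand: T7(19) + synthesis(8) + left buffer(50) +
    payload + right buffer(50) + polyA(10).
    """

    t7_promoter: str = _T7_PROMOTER
    synthesis_buffer: str = _SYNTH_BUFFER
    left_buffer: str = _LEFT_BUFFER
    right_buffer: str = _RIGHT_BUFFER
    poly_a: str = "A" * 10

    @property
    def prefix(self) -> str:
        return self.t7_promoter + self.synthesis_buffer + self.left_buffer

    @property
    def suffix(self) -> str:
        return self.right_buffer + self.poly_a

    @property
    def overhead_bases(self) -> int:
        return len(self.prefix) + len(self.suffix)

    def full_length(self, payload_bases: int) -> int:
        return self.overhead_bases + payload_bases

    def payload_span(self, payload_bases: int) -> tuple[int, int]:
        start = len(self.prefix)
        return (start, start + payload_bases)

    def assemble(self, payload: str) -> str:
        return self.prefix + payload + self.suffix

    def recent_seed(self, params: CodeParams) -> bytes:
        """Codes of the buffer tail used to seed constraint windows."""
        w = params.recent_window
        return seq_to_codes(self.left_buffer[-w:], DNA_ALPHABET)


@dataclass(frozen=True)
class MessageRecord:
    """Serialized unit: index bytes, CRC-8 over them, then payload."""

    index_bytes: bytes
    crc_byte: int
    payload_bytes: bytes

    @classmethod
    def build(cls, index: int, payload: bytes, index_width: int = 2) -> "MessageRecord":
        idx = index.to_bytes(index_width, "big")
        return cls(index_bytes=idx, crc_byte=crc8(idx), payload_bytes=payload)

    @property
    def index(self) -> int:
        return int.from_bytes(self.index_bytes, "big")

    @property
    def crc_ok(self) -> bool:
        return crc8(self.index_bytes) == self.crc_byte

    def to_bytes(self) -> bytes:
        return self.index_bytes + bytes([self.crc_byte]) + self.payload_bytes

    def to_bits(self) -> list[int]:
        return bytes_to_bits(self.to_bytes())

    @classmethod
    def from_bits(cls, bits: Sequence[int], index_width: int = 2) -> "MessageRecord":
        raw = bits_to_bytes(bits)
        if len(raw) < index_width + 1:
            raise ValueError("bit string too short for header")
        return cls(
            index_bytes=raw[:index_width],
            crc_byte=raw[index_width],
            payload_bytes=raw[index_width + 1 :],
        )


# ---------------------------------------------------------------------------
# base selection
# ---------------------------------------------------------------------------

def _next_base_code(history: int, base_index: int, bit: int,
                    recent: Sequence[int], params: CodeParams) -> int:
    # the bit is NOT digested: it indexes the candidate ordering, so the
    # two bit guesses always emit distinct bases (see _pick_base)
    perm = _PERMS[_digest(history, base_index, 0, params.salt) % 24]
    return _pick_base(perm, recent, bit, params.max_homopolymer,
                      params.gc_window, params.gc_target, params.gc_tolerance)


def next_base(history: int, base_index: int, bit: int, recent_bases: str,
              params: CodeParams) -> str:
    """Emit the constrained, hash-ranked base for one encoder step.

    ``recent_bases`` is the suffix of the already-emitted sequence; it must
    be long enough to evaluate the homopolymer and GC-window constraints
    (shorter prefixes are handled with shrunken windows).
    """
    recent = seq_to_codes(recent_bases, params.alphabet)
    code = _next_base_code(history, base_index, bit, recent, params)
    return params.alphabet[code]


def _next_base_batch(histories: np.ndarray, base_index: int, bit: int,
                     recent: np.ndarray, params: CodeParams) -> np.ndarray:
    """Vectorised `_next_base_code` for decoders.

    ``recent`` is an (S, W) uint8 matrix of base codes with W =
    ``params.recent_window`` (windows always full: decoders seed them from
    the layout's left buffer).  Must agree exactly with the scalar path.
    """
    S, W = recent.shape
    assert W == params.recent_window
    perm_idx = (_digest_batch(histories, base_index, 0, params.salt)
                % np.uint64(24)).astype(np.intp)
    cand = _PERMS_ARR[perm_idx]  # (S, 4) candidate codes in rank order

    hp = params.max_homopolymer
    tail = recent[:, W - hp :]
    run = np.all(tail == tail[:, :1], axis=1)
    forbid = np.where(run, recent[:, -1].astype(np.int16), np.int16(-1))

    w = params.gc_window
    win = recent[:, W - (w - 1) :]
    g = np.sum((win == 1) | (win == 2), axis=1)

    valid = cand != forbid[:, None].astype(cand.dtype)
    isgc = (cand == 1) | (cand == 2)
    dev = np.abs((g[:, None] + isgc) / float(w) - params.gc_target)
    ok = dev <= params.gc_tolerance + 1e-12

    # mirror _pick_base: GC-tolerant candidates first (rank order), then
    # by ascending deviation, invalid last; the bit indexes the ordering
    keys = np.where(valid, np.where(ok, 0.0, 1.0 + dev), np.inf)
    order = np.argsort(keys, axis=1, kind="stable")
    sel = order[np.arange(S), bit]
    return cand[np.arange(S), sel]


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def payload_length(params: CodeParams, n_payload_bytes: int) -> int:
    """Number of payload bases for a given payload size (header included)."""
    return params.total_bits(n_payload_bytes) * params.period


def encode_bits(bits: Sequence[int], params: CodeParams,
                recent_seed: bytes = b"") -> str:
    """Map a raw bit string to constrained bases (no header, no layout)."""
    recent = list(recent_seed)
    history = 0
    out: list[int] = []
    consumed = 0
    n_steps = len(bits) * params.period
    for j in range(n_steps):
        if params.is_bit_step(j):
            bit = bits[consumed]
            consumed += 1
        else:
            bit = 0
        code = _next_base_code(history, j, bit, recent, params)
        out.append(code)
        recent.append(code)
        if params.is_bit_step(j):
            history = ((history << 1) | bit) & params.history_mask
    assert consumed == len(bits)
    return codes_to_seq(out, params.alphabet)


def encode_payload_region(record: MessageRecord, params: CodeParams,
                          layout: StrandLayout) -> str:
    if len(record.payload_bytes) > params.max_payload_bytes:
        raise ValueError("payload too long")
    return encode_bits(record.to_bits(), params, layout.recent_seed(params))


def encode(record: MessageRecord, params: CodeParams,
           layout: StrandLayout | None = None) -> str:
    """Serialize a record to a full strand (fixed regions + payload)."""
    layout = layout or StrandLayout()
    return layout.assemble(encode_payload_region(record, params, layout))


def reverse_complement(sequence: str, alphabet: Sequence[str] = DNA_ALPHABET) -> str:
    """Reverse complement over DNA or RNA alphabets (involution)."""
    comp = {alphabet[0]: alphabet[3], alphabet[3]: alphabet[0],
            alphabet[1]: alphabet[2], alphabet[2]: alphabet[1]}
    try:
        return "".join(comp[c] for c in reversed(sequence))
    except KeyError as exc:
        raise ValueError(f"invalid symbol {exc} for alphabet {alphabet}") from exc
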