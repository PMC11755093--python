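"""Synthetic CTC-matrix generation, CTC math, file I/O and buffer trimming.

The simulator stands in for a nanopore basecaller's ML model: it emits a
T x (|alphabet|+1) matrix of per-time-step log probabilities (column 0 is
the blank symbol) with dwell-time variation, blank-dominated separator
columns between repeated bases, miscall noise, skips and stutters.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import h5py
import numpy as np

from .hedges_code import DNA_ALPHABET, StrandLayout, seq_to_codes

__all__ = [
    "BLANK",
    "CTCMatrix",
    "SimConfig",
    "simulate_ctc",
    "collapse",
    "greedy_basecall",
    "forward_probability",
    "trim_and_orient",
    "reverse_complement_ctc",
    "save_ctc",
    "load_ctc",
    "save_batch",
    "load_batch",
    "OrientationAmbiguousWarning",
]

BLANK = "-"

# probability floor applied before taking logs; keeps arithmetic finite
# except for structurally impossible transitions
LOG_EPS = -30.0


class OrientationAmbiguousWarning(UserWarning):
    """Raised when forward/reverse-complement scores are too close to call."""


@dataclass
class CTCMatrix:
    """T x (|alphabet|+1) log-probability matrix; column 0 is blank."""

    logp: np.ndarray
    alphabet: tuple[str, ...] = DNA_ALPHABET
    provenance: str = "simulated"

    def __post_init__(self) -> None:
        self.logp = np.asarray(self.logp, dtype=np.float64)
        self.alphabet = tuple(self.alphabet)
        if self.logp.ndim != 2 or self.logp.shape[1] != len(self.alphabet) + 1:
            raise ValueError("logp must be T x (|alphabet|+1)")
        if self.logp.shape[0] < 1:
            raise ValueError("T must be >= 1")

    @property
    def T(self) -> int:
        return self.logp.shape[0]

    def validate(self, atol: float = 1e-9) -> None:
        if np.any(self.logp > 1e-12):
            raise ValueError("log probabilities must be <= 0")
        from scipy.special import logsumexp

        rows = logsumexp(self.logp, axis=1)
        if not np.allclose(rows, 0.0, atol=atol):
            raise ValueError("rows must each sum to probability 1")


@dataclass(frozen=True)
class SimConfig:
    """Generative knobs for the synthetic basecaller output.

    ``dwell_mean`` is the expected number of CTC steps per base;
    ``blank_weight`` routes mass to blank within a base's dwell;
    ``miscall_rate`` is the probability a base's dwell carries a wrong
    label (substitution-like, flips the per-row argmax); ``skip_rate``
    drops a base entirely (deletion-like); ``stutter_rate`` inserts an
    extra blank-dominated step (insertion-like); ``temperature`` flattens
    rows toward uniform (softens every column without moving the argmax).
    """

    dwell_mean: float = 2.5
    blank_weight: float = 0.15
    miscall_rate: float = 0.0
    skip_rate: float = 0.0
    stutter_rate: float = 0.0
    temperature: float = 0.0

    def __post_init__(self) -> None:
        for name in ("blank_weight", "miscall_rate", "skip_rate",
                     "stutter_rate", "temperature"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.dwell_mean < 1.0:
            raise ValueError("dwell_mean must be >= 1")
        if self.blank_weight >= 0.5:
            raise ValueError("blank_weight must be < 0.5 so the dwell label "
                             "dominates its rows")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**{k: v for k, v in d.items() if k != "seed"})


def _finalize_rows(rows: list[np.ndarray], temperature: float,
                   alphabet: tuple[str, ...], provenance: str) -> CTCMatrix:
    mat = np.vstack(rows)
    n = mat.shape[1]
    if temperature > 0.0:
        mat = (1.0 - temperature) * mat + temperature / n
    mat = np.maximum(mat, np.exp(LOG_EPS))
    mat /= mat.sum(axis=1, keepdims=True)
    return CTCMatrix(np.log(mat), alphabet, provenance)


def simulate_ctc(sequence: str, config: SimConfig,
                 rng: np.random.Generator) -> CTCMatrix:
    """Emulate basecaller CTC output for a known template sequence.

    Per base: dwell ~ Geometric(1/dwell_mean) steps (mean ``dwell_mean``),
    each step placing ``1 - blank_weight`` on the dwell's label; with
    probability ``miscall_rate`` the label is a wrong base for the whole
    dwell.  A blank-dominated separator row is always emitted between equal
    adjacent template bases, so at miscall_rate = skip_rate = 0 the greedy
    argmax path collapses back to the input exactly.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    alphabet = DNA_ALPHABET if "U" not in sequence else ("A", "C", "G", "U")
    codes = seq_to_codes(sequence, alphabet)
    A = len(alphabet)
    bw = config.blank_weight

    def base_row(code: int) -> np.ndarray:
        row = np.zeros(A + 1)
        row[0] = bw
        row[code + 1] = 1.0 - bw
        return row

    def blank_row() -> np.ndarray:
        row = np.zeros(A + 1)
        row[0] = 1.0
        return row

    rows: list[np.ndarray] = []
    prev_emitted = -1
    for code in codes:
        if config.skip_rate > 0.0 and rng.random() < config.skip_rate:
            continue
        label = code
        if config.miscall_rate > 0.0 and rng.random() < config.miscall_rate:
            label = (code + int(rng.integers(1, A))) % A
        if label == prev_emitted:
            rows.append(blank_row())
        dwell = 1 if config.dwell_mean == 1.0 else int(
            rng.geometric(1.0 / config.dwell_mean)
        )
        for _ in range(dwell):
            rows.append(base_row(label))
        if config.stutter_rate > 0.0 and rng.random() < config.stutter_rate:
            rows.append(blank_row())
        prev_emitted = label
    if not rows:
        rows.append(blank_row())
    return _finalize_rows(rows, config.temperature, alphabet, "simulated")


# ---------------------------------------------------------------------------
# CTC math
# ---------------------------------------------------------------------------

def collapse(path: str, blank: str = BLANK) -> str:
    """Standard CTC collapse: merge adjacent repeats, then drop blanks."""
    out = []
    prev = None
    for c in path:
        if c != prev:
            if c != blank:
                out.append(c)
            prev = c
    return "".join(out)


def greedy_basecall(ctc: CTCMatrix) -> tuple[str, list[int]]:
    """Per-row argmax path collapsed under CTC rules.

    Returns the sequence and, per emitted symbol, the time step at which
    its run starts (used to map sequence positions back to time).
    """
    arg = np.argmax(ctc.logp, axis=1)
    seq: list[str] = []
    times: list[int] = []
    prev = -1
    for t, a in enumerate(arg):
        if a != prev and a != 0:
            seq.append(ctc.alphabet[a - 1])
            times.append(t)
        prev = a
    return "".join(seq), times


def _extended_labels(codes: bytes) -> np.ndarray:
    ext = [0]
    for c in codes:
        ext.extend((c + 1, 0))
    return np.array(ext, dtype=np.intp)


def forward_probability(message: str, ctc: CTCMatrix) -> float:
    """Log of the summed probability of all CTC-encodings of ``message``.

    Standard forward recursion over the blank-extended label sequence;
    returns ``-inf`` when no length-T path can encode the message.
    """
    lp = ctc.logp
    T = ctc.T
    codes = seq_to_codes(message, ctc.alphabet)
    if len(codes) > T:
        return -np.inf
    ext = _extended_labels(codes)
    S = len(ext)
    neg = -np.inf
    alpha = np.full(S, neg)
    alpha[0] = lp[0, 0]
    if S > 1:
        alpha[1] = lp[0, ext[1]]
    if S > 2:
        allow_skip = np.zeros(S, dtype=bool)
        allow_skip[2:] = (ext[2:] != 0) & (ext[2:] != ext[:-2])
    else:
        allow_skip = np.zeros(S, dtype=bool)
    for t in range(1, T):
        prev1 = np.concatenate(([neg], alpha[:-1]))
        acc = np.logaddexp(alpha, prev1)
        if S > 2:
            prev2 = np.concatenate(([neg, neg], alpha[:-2]))
            acc = np.where(allow_skip, np.logaddexp(acc, prev2), acc)
        alpha = lp[t, ext] + acc
    if S == 1:
        return float(alpha[0])
    return float(np.logaddexp(alpha[-1], alpha[-2]))


# ---------------------------------------------------------------------------
# orientation and trimming
# ---------------------------------------------------------------------------

def reverse_complement_ctc(ctc: CTCMatrix) -> CTCMatrix:
    """Time-reversed matrix with complement-permuted base columns."""
    perm = np.array([0, 4, 3, 2, 1])
    return CTCMatrix(ctc.logp[::-1][:, perm].copy(), ctc.alphabet,
                     ctc.provenance)


def _best_match(seq: bytes, pattern: bytes) -> tuple[int, int]:
    """Best sliding Hamming match of ``pattern`` in ``seq``: (pos, matches)."""
    n, m = len(seq), len(pattern)
    if n < m or m == 0:
        return 0, 0
    s = np.frombuffer(seq, dtype=np.uint8)
    p = np.frombuffer(pattern, dtype=np.uint8)
    scores = np.zeros(n - m + 1, dtype=np.int32)
    for j in range(m):
        scores += s[j : j + n - m + 1] == p[j]
    pos = int(np.argmax(scores))
    return pos, int(scores[pos])


def _buffer_score(ctc: CTCMatrix, layout: StrandLayout) -> tuple[int, dict]:
    seq, times = greedy_basecall(ctc)
    codes = seq_to_codes(seq, ctc.alphabet)
    lb = seq_to_codes(layout.left_buffer)
    rb = seq_to_codes(layout.right_buffer)
    pl, sl = _best_match(codes, lb)
    # right buffer must come after the left one
    tail_off = pl + len(lb)
    pr_rel, sr = _best_match(codes[tail_off:], rb)
    pr = tail_off + pr_rel
    return sl + sr, {"seq": seq, "times": times, "left_end": tail_off,
                     "right_start": pr}


def trim_and_orient(ctc: CTCMatrix, layout: StrandLayout,
                    margin_threshold: int = 10) -> tuple[CTCMatrix, str]:
    """Locate buffer regions, pick strand orientation, cut out the payload.

    The orientation whose greedy basecalls better match the layout's buffer
    sequences wins; the returned matrix is restricted to the time steps
    between the located buffer boundaries.  A close score margin raises
    :class:`OrientationAmbiguousWarning`.
    """
    fwd_score, fwd = _buffer_score(ctc, layout)
    rc = reverse_complement_ctc(ctc)
    rev_score, rev = _buffer_score(rc, layout)
    if abs(fwd_score - rev_score) < margin_threshold:
        warnings.warn("orientation ambiguous: buffer score margin "
                      f"{abs(fwd_score - rev_score)} < {margin_threshold}",
                      OrientationAmbiguousWarning)
    if fwd_score >= rev_score:
        orientation, mat, info = "forward", ctc, fwd
    else:
        orientation, mat, info = "reverse_complement", rc, rev
    times = info["times"]
    i0, i1 = info["left_end"], info["right_start"]
    if not times or i0 >= len(times):
        return mat, orientation
    t0 = times[i0]
    t1 = times[i1] if i1 < len(times) else mat.T
    if t1 <= t0:
        return mat, orientation
    return CTCMatrix(mat.logp[t0:t1].copy(), mat.alphabet, mat.provenance), orientation


# ---------------------------------------------------------------------------
# file I/O: NPY + JSON sidecar, HDF5 batches
# ---------------------------------------------------------------------------

def save_ctc(path: str | Path, ctc: CTCMatrix) -> None:
    path = Path(path)
    np.save(path.with_suffix(".npy"), ctc.logp)
    sidecar = {"alphabet": list(ctc.alphabet), "provenance": ctc.provenance}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_ctc(path: str | Path) -> CTCMatrix:
    path = Path(path)
    logp = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return CTCMatrix(logp, tuple(meta["alphabet"]),
                     meta.get("provenance", "loaded"))


def save_batch(path: str | Path, matrices: list[CTCMatrix],
               read_ids: list[str] | None = None) -> None:
    read_ids = read_ids or [f"read_{i}" for i in range(len(matrices))]
    with h5py.File(path, "w") as f:
        for rid, m in zip(read_ids, matrices):
            g = f.create_group(rid)
            g.create_dataset("logp", data=m.logp)
            g.attrs["alphabet"] = ",".join(m.alphabet)
            g.attrs["provenance"] = m.provenance


def load_batch(path: str | Path) -> dict[str, CTCMatrix]:
    out: dict[str, CTCMatrix] = {}
    with h5py.File(path, "r") as f:
        for rid in f:
            g = f[rid]
            out[rid] = CTCMatrix(
                g["logp"][()],
                tuple(g.attrs["alphabet"].split(",")),
                str(g.attrs.get("provenance", "loaded")),
            )
    return out
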