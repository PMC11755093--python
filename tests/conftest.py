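"""Shared fixtures and independent brute-force oracles.

The oracles enumerate CTC paths directly (no forward recursions) so they
stay independent of the code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from poretrellis import CodeParams, StrandLayout
from poretrellis.ctc_sim import CTCMatrix


@pytest.fixture
def params() -> CodeParams:
    return CodeParams(rate_id="1/2", history_bits=4, salt=7)

@pytest.fixture
def layout() -> StrandLayout:
    return StrandLayout()

@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_ctc(T: int, rng: np.random.Generator, alphabet=("A", "C", "G", "T"),
               concentration: float = 1.0) -> CTCMatrix:
    """Random normalized log-probability matrix (Dirichlet rows)."""
    mat = rng.dirichlet(np.full(len(alphabet) + 1, concentration), size=T)
    mat = np.maximum(mat, 1e-12)
    mat /= mat.sum(axis=1, keepdims=True)
    return CTCMatrix(np.log(mat), alphabet)


def enumerate_message_probs(ctc: CTCMatrix) -> dict[str, float]:
    """Brute force: probability of every collapsed message, by full path
    enumeration over the (A+1)^T path space.  Returns log probabilities."""
    A = len(ctc.alphabet)
    prob = ctc.logp
    T = ctc.T
    acc: dict[tuple, float] = {}

    def rec(t: int, last: int, collapsed: tuple, logp: float) -> None:
        if t == T:
            acc[collapsed] = acc.get(collapsed, 0.0) + np.exp(logp)
            return
        for s in range(A + 1):
            c2 = collapsed
            if s != 0 and s != last:
                c2 = collapsed + (s,)
            rec(t + 1, s, c2, logp + prob[t, s])

    rec(0, 0, (), 0.0)
    return {"".join(ctc.alphabet[c - 1] for c in key): float(np.log(v))
            for key, v in acc.items()}


def enumerate_prefix_alphas(target: str, ctc: CTCMatrix):
    """Brute force forward variables for every prefix of ``target``.

    Returns (nonblank, blank): arrays of shape (len(target)+1, T) where
    nonblank[i, t] is the summed probability of all length-(t+1) paths that
    collapse to target[:i] and end on a non-blank symbol, and blank[i, t]
    the same for paths ending on blank.  Path enumeration is pruned to
    paths whose collapse stays a prefix of ``target`` (pure counting, no
    recurrences shared with the implementation).
    """
    codes = [ctc.alphabet.index(c) + 1 for c in target]
    T = ctc.T
    n = len(codes)
    A = len(ctc.alphabet)
    prob = np.exp(ctc.logp)
    nonblank = np.zeros((n + 1, T))
    blank = np.zeros((n + 1, T))

    def rec(t: int, clen: int, last: int, p: float) -> None:
        if last == 0:
            blank[clen, t] += p
        else:
            nonblank[clen, t] += p
        if t + 1 == T:
            return
        for s in range(A + 1):
            if s == 0 or s == last:
                rec(t + 1, clen, s, p * prob[t + 1, s])
            elif clen < n and s == codes[clen]:
                rec(t + 1, clen + 1, s, p * prob[t + 1, s])

    rec(0, 0, 0, prob[0, 0])
    for s in range(1, A + 1):
        if n >= 1 and s == codes[0]:
            rec(0, 1, s, prob[0, s])
    return nonblank, blank
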