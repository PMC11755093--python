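"""Numba inner loops for the alignment-matrix trellis decoder.

Pure-python fallbacks keep the package importable without numba; they are
numerically identical, only slower.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap

_NEG_INF = -np.inf


@njit(cache=True, inline="always")
def _ladd2(a, b):
    if a == _NEG_INF:
        return b
    if b == _NEG_INF:
        return a
    if a < b:
        a, b = b, a
    return a + math.log1p(math.exp(b - a))


@njit(cache=True, inline="always")
def _ladd3(a, b, c):
    return _ladd2(_ladd2(a, b), c)


@njit(cache=True)
def _logsumexp_row(row):
    m = _NEG_INF
    for v in row:
        if v > m:
            m = v
    if m == _NEG_INF:
        return _NEG_INF
    s = 0.0
    for v in row:
        s += math.exp(v - m)
    return m + math.log(s)


@njit(cache=True)
def extend_one(P, lb, lc, same, is_first, Q, R):
    """Derive the interleaved-blank row Q and new-base row R from base row P.

    ``lb``/``lc`` are the blank / new-base log-probability columns.  When
    ``same`` the direct skip term from P is dropped (a blank must separate
    repeats).  ``is_first`` marks extension from the empty-prefix blank row,
    whose conceptual value at t = -1 is log 1 = 0.
    """
    T = P.shape[0]
    qm1 = _NEG_INF
    rm1 = _NEG_INF
    pm1 = 0.0 if is_first else _NEG_INF
    for t in range(T):
        if is_first:
            # blank row before the first base is the empty-prefix row itself
            Q[t] = P[t]
            rt = lc[t] + _ladd2(rm1, pm1)
        else:
            qt = lb[t] + _ladd2(qm1, pm1)
            if same:
                rt = lc[t] + _ladd2(rm1, qm1)
            else:
                rt = lc[t] + _ladd3(rm1, qm1, pm1)
            Q[t] = qt
            qm1 = qt
        R[t] = rt
        rm1 = rt
        pm1 = P[t]


@njit(cache=True)
def am_step(prev_rows, prev_alive, lp, bases, preds, nedge, same, is_first,
            out_rows, out_score, out_edge, scratch):
    """One trellis level: extend every state's row along its incoming edges
    and keep the max-score survivor.

    prev_rows : (S, T) base rows of the surviving prefixes
    lp        : (T, A+1) CTC log probabilities, column 0 blank
    bases     : (S, 2) emitted base code per destination edge
    preds     : (S, 2) predecessor state per destination edge
    nedge     : (S,) number of incoming edges (1 on non-bit steps)
    same      : (S, 2) repeat-base flag per edge
    scratch   : (2, T) candidate row workspace — the only per-edge storage
    """
    S, T = out_rows.shape
    for s in range(S):
        best = _NEG_INF
        best_e = -1
        for e in range(nedge[s]):
            p = preds[s, e]
            if not prev_alive[p]:
                continue
            b = bases[s, e]
            qm1 = _NEG_INF
            rm1 = _NEG_INF
            pm1 = 0.0 if is_first else _NEG_INF
            row = scratch[e]
            for t in range(T):
                if is_first:
                    rt = lp[t, b + 1] + _ladd2(rm1, pm1)
                else:
                    qt = lp[t, 0] + _ladd2(qm1, pm1)
                    if same[s, e]:
                        rt = lp[t, b + 1] + _ladd2(rm1, qm1)
                    else:
                        rt = lp[t, b + 1] + _ladd3(rm1, qm1, pm1)
                    qm1 = qt
                row[t] = rt
                rm1 = rt
                pm1 = prev_rows[p, t]
            sc = _logsumexp_row(row)
            if sc > best:
                best = sc
                best_e = e
        out_score[s] = best
        out_edge[s] = best_e
        if best_e >= 0:
            for t in range(T):
                out_rows[s, t] = scratch[best_e, t]
        else:
            for t in range(T):
                out_rows[s, t] = _NEG_INF
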