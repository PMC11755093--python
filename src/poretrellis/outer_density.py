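"""Reed-Solomon outer-code design and system density model.

Residual byte errors left by the inner decoder are modelled as i.i.d.
across diagonally striped strands; a codeword fails when more than
floor((n-k)/2) of its n bytes are wrong.  The design point picks the
largest k whose expected codeword failures over capacity * MTTF accesses
stay below one, and the density phi folds in the inner code rate and all
fixed strand overheads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .hedges_code import CodeParams, StrandLayout, payload_length

__all__ = ["DensityModel", "mean_byte_error", "rs_failure_prob",
           "choose_design", "density", "strand_density", "density_sweep"]


@dataclass
class DensityModel:
    p_byte: float
    rs_n: int
    rs_k: Optional[int]
    capacity_bytes: float
    mttf_accesses: float
    strand_overhead: int
    index_crc_bases: float
    rate: float
    phi: Optional[float]

    @property
    def feasible(self) -> bool:
        return self.rs_k is not None


def mean_byte_error(profiles: Sequence[np.ndarray]) -> float:
    """Unweighted mean byte error rate over positions, then strands."""
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    return float(np.mean([np.mean(p) for p in profiles]))


def rs_failure_prob(n: int, k: int, p_byte: float) -> float:
    """P[codeword undecodable] = P[X > floor((n-k)/2)], X ~ Binomial(n, p).

    Stable log-space tail summation.
    """
    if not 0 <= p_byte <= 1:
        raise ValueError("p_byte must be in [0, 1]")
    if not 0 < k < n:
        raise ValueError("require 0 < k < n")
    t = (n - k) // 2
    if p_byte == 0.0:
        return 0.0
    if p_byte == 1.0:
        return 1.0
    i = np.arange(t + 1, n + 1)
    logc = gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
    logpmf = logc + i * np.log(p_byte) + (n - i) * np.log1p(-p_byte)
    return float(np.exp(logsumexp(logpmf)))


def choose_design(p_byte: float, capacity_bytes: float = 1e12,
                  mttf_accesses: float = 1e6, n: int = 255,
                  max_k: Optional[int] = None) -> Optional[int]:
    """Largest k meeting the capacity/MTTF constraint, or None if infeasible.

    The constraint: expected codeword failures over ``capacity * mttf``
    accesses stay below 1, i.e. per-codeword failure probability is at most
    ``k / (capacity_bytes * mttf_accesses)`` (capacity/k codewords).
    """
    if not 0 <= p_byte <= 1:
        raise ValueError("p_byte must be in [0, 1]")
    max_k = max_k if max_k is not None else n - 1
    if p_byte == 0.0:
        return max_k
    for k in range(max_k, 0, -1):
        budget = k / (capacity_bytes * mttf_accesses)
        if rs_failure_prob(n, k, p_byte) <= budget:
            return k
    return None


def density(rate: float, payload_bases: int, info_bits: float,
            overhead_bases: int = 0, rs_k: int = 255, rs_n: int = 255) -> float:
    """phi in bits/base: outer-code rate x net information per strand base.

    ``info_bits`` counts true payload bits (index/CRC header excluded);
    ``rs_k == rs_n`` models the no-outer-code limit.
    """
    if payload_bases <= 0:
        raise ValueError("payload_bases must be positive")
    total = payload_bases + overhead_bases
    phi = (rs_k / rs_n) * info_bits / total
    assert phi <= rate + 1e-12, "overheads can only reduce density"
    return phi


def strand_density(params: CodeParams, layout: StrandLayout,
                   n_payload_bytes: int, rs_k: Optional[int],
                   rs_n: int = 255) -> Optional[float]:
    """phi for a concrete strand design; None when the design is infeasible."""
    if rs_k is None:
        return None
    payload_bases = payload_length(params, n_payload_bytes)
    info_bits = n_payload_bytes * 8
    return density(params.rate, payload_bases, info_bits,
                   layout.overhead_bases, rs_k, rs_n)


def density_sweep(profile: np.ndarray, params: CodeParams,
                  layout: StrandLayout, byte_lengths: Sequence[int],
                  capacity_bytes: float = 1e12, mttf_accesses: float = 1e6,
                  rs_n: int = 255) -> list[DensityModel]:
    """Project phi over candidate strand lengths.

    The measured positional byte-error profile is truncated at each
    candidate payload size to emulate shorter strands, the mean error rate
    recomputed and the outer code re-chosen.
    """
    profile = np.asarray(profile, dtype=float)
    out: list[DensityModel] = []
    for n_bytes in byte_lengths:
        if n_bytes < 1 or n_bytes > len(profile):
            raise ValueError("byte length outside profile range")
        p_bar = float(profile[:n_bytes].mean())
        rs_k = choose_design(p_bar, capacity_bytes, mttf_accesses, rs_n)
        phi = strand_density(params, layout, n_bytes, rs_k, rs_n)
        header_bases = params.header_bytes * 8 * params.period
        out.append(DensityModel(
            p_byte=p_bar, rs_n=rs_n, rs_k=rs_k,
            capacity_bytes=capacity_bytes, mttf_accesses=mttf_accesses,
            strand_overhead=layout.overhead_bases,
            index_crc_bases=header_bases, rate=params.rate, phi=phi,
        ))
    return out
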