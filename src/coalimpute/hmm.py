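"""Diploid haplotype-copying HMM baseline for genotype imputation.

The comparator models each study individual's genotype vector as emitted
by an (unobserved) ordered pair of reference haplotypes that is copied
along the sequence, with per-site miscopying (mutation) and Markov
switching between copied haplotypes driven by the recombination map.  In
LD-block mode the recombination rate is zero, the copying pair is
constant along the sequence, and the posterior reduces to a weighted
enumeration of the N^2 ordered reference pairs; a forward-backward
implementation over the pair chain supports nonzero rates and doubles as
an independent code path for the rho = 0 case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .impute import GenotypePosterior, call_genotypes
from .simulate import Cohort

__all__ = [
    "HMMParams",
    "li_stephens_epsilon",
    "emission_prob",
    "impute_diploid",
    "impute_cohort_hmm",
]


def li_stephens_epsilon(n_ref: int) -> float:
    """Population-genetic default for the per-allele miscopy probability:
    ``theta~ / (2 (theta~ + N))`` with ``theta~ = 1 / sum_{i<N} 1/i``."""
    if n_ref < 2:
        return 1e-8
    theta = 1.0 / np.sum(1.0 / np.arange(1, n_ref))
    return float(theta / (2.0 * (theta + n_ref)))


@dataclass(frozen=True)
class HMMParams:
    """Copying-model parameters.

    ``miscopy_epsilon`` is the probability that an emitted allele differs
    from the copied haplotype's allele (``None`` selects the N-dependent
    Li-Stephens default); ``rho_map`` holds per-interval switching
    intensities (recombination rate scaled by 4*N_e), a scalar applying to
    every interval -- 0 for LD-block imputation.
    """

    miscopy_epsilon: float | None = None
    rho_map: float | np.ndarray = 0.0

    def epsilon_for(self, n_ref: int) -> float:
        eps = self.miscopy_epsilon
        if eps is None:
            return li_stephens_epsilon(n_ref)
        if not 0 <= eps < 0.5:
            raise ValueError("miscopy_epsilon must lie in [0, 0.5)")
        return float(eps)

    def rho_intervals(self, n_sites: int) -> np.ndarray:
        rho = np.asarray(self.rho_map, dtype=float)
        if rho.ndim == 0:
            rho = np.full(max(n_sites - 1, 0), float(rho))
        if rho.size != max(n_sites - 1, 0):
            raise ValueError("rho_map must have one entry per between-site interval")
        if np.any(rho < 0):
            raise ValueError("recombination rates must be non-negative")
        return rho


# ----------------------------------------------------------------------
def emission_prob(g, copied_alleles, epsilon: float) -> float:
    """P(observed genotype ``g`` | copied alleles), each copied allele
    flipping independently with probability ``epsilon``.  A missing
    genotype (``None`` or negative) is marginalised out (probability 1)."""
    if g is None or (isinstance(g, (int, np.integer)) and g < 0):
        return 1.0
    if g not in (0, 1, 2):
        raise ValueError(f"invalid genotype code {g!r}")
    a1, a2 = copied_alleles
    if a1 not in (0, 1) or a2 not in (0, 1):
        raise ValueError("copied alleles must be binary")
    p1 = a1 * (1 - epsilon) + (1 - a1) * epsilon  # P(emitted allele 1 is derived)
    p2 = a2 * (1 - epsilon) + (1 - a2) * epsilon
    table = {
        0: (1 - p1) * (1 - p2),
        1: p1 * (1 - p2) + (1 - p1) * p2,
        2: p1 * p2,
    }
    return float(table[g])


def _emit_one(p_derived: np.ndarray, g: int) -> np.ndarray:
    """Vectorised genotype emission over ordered pairs.

    ``p_derived[i]`` is the probability haplotype i emits the derived
    allele at the site; returns the (N, N) matrix of P(g | pair)."""
    p1 = p_derived[:, None]
    p2 = p_derived[None, :]
    if g == 0:
        return (1 - p1) * (1 - p2)
    if g == 1:
        return p1 * (1 - p2) + (1 - p1) * p2
    return p1 * p2


def _pair_posteriors(logw: np.ndarray) -> np.ndarray:
    w = np.exp(logw - logw.max())
    return w / w.sum()


def _pair_enumeration_posterior(G, H, eps):
    """Posterior over missing genotypes with a constant copying pair
    (rho = 0): direct weighted enumeration of the N^2 ordered pairs."""
    N, L = H.shape
    p_derived = H * (1 - eps) + (1 - H) * eps  # (N, L)
    logw = np.zeros((N, N))
    for j in range(L):
        if G[j] < 0:
            continue
        logw += np.log(_emit_one(p_derived[:, j], int(G[j])))
    w = _pair_posteriors(logw)
    missing = np.flatnonzero(G < 0)
    probs = np.empty((missing.size, 3))
    for k, j in enumerate(missing):
        for g in (0, 1, 2):
            probs[k, g] = float(np.sum(w * _emit_one(p_derived[:, j], g)))
    return missing, probs


def _chain_step(mat: np.ndarray, s: float) -> np.ndarray:
    """Apply the factorised pair transition (each haplotype independently
    keeps its state w.p. 1-s or resamples uniformly w.p. s) to a joint
    (N, N) distribution-like array."""
    if s == 0.0:
        return mat
    N = mat.shape[0]
    row = mat.sum(axis=0, keepdims=True) / N  # switch first index
    col = mat.sum(axis=1, keepdims=True) / N  # switch second index
    tot = mat.sum() / (N * N)
    return (
        (1 - s) * (1 - s) * mat
        + s * (1 - s) * row
        + (1 - s) * s * col
        + s * s * tot
    )


def _forward_backward_posterior(G, H, eps, rho):
    """Posterior over missing genotypes by forward-backward over the
    ordered-pair chain with per-interval switch intensity ``rho``."""
    N, L = H.shape
    p_derived = H * (1 - eps) + (1 - H) * eps
    switch = 1.0 - np.exp(-np.asarray(rho, dtype=float) / N)

    def emit(j):
        if G[j] < 0:
            return None
        return _emit_one(p_derived[:, j], int(G[j]))

    fwd = np.empty((L, N, N))
    cur = np.full((N, N), 1.0 / (N * N))
    for j in range(L):
        if j > 0:
            cur = _chain_step(cur, switch[j - 1])
        e = emit(j)
        if e is not None:
            cur = cur * e
        norm = cur.sum()
        cur = cur / norm
        fwd[j] = cur
    bwd = np.ones((N, N))
    missing = np.flatnonzero(G < 0)
    probs = np.empty((missing.size, 3))
    out = {}
    for j in range(L - 1, -1, -1):
        gamma = fwd[j] * bwd
        gamma = gamma / gamma.sum()
        if G[j] < 0:
            out[j] = np.array([
                float(np.sum(gamma * _emit_one(p_derived[:, j], g))) for g in (0, 1, 2)
            ])
        e = emit(j)
        msg = bwd if e is None else bwd * e
        if j > 0:
            bwd = _chain_step(msg, switch[j - 1])
            bwd = bwd / bwd.max()
    for k, j in enumerate(missing):
        probs[k] = out[j]
    return missing, probs


def impute_diploid(
    G,
    H,
    params: HMMParams | None = None,
    ref_freq=None,
    method: str = "auto",
):
    """Impute the missing entries of one genotype vector.

    Parameters
    ----------
    G
        Genotype vector over all L sites; entries in {0, 1, 2} or negative
        for missing.
    H
        Reference panel, (N, L) binary array.
    method
        ``enumeration`` (constant copying pair; requires rho = 0),
        ``forward-backward``, or ``auto`` (enumeration when every rho is
        zero).

    Returns ``(missing_idx, probs, best_guess)``.
    """
    params = HMMParams() if params is None else params
    G = np.asarray(G, dtype=np.int8)
    H = np.asarray(H, dtype=np.float64)
    if H.ndim != 2 or H.shape[0] < 1:
        raise ValueError("reference panel must be a non-empty (N, L) matrix")
    if H.shape[1] != G.size:
        raise ValueError("panel and genotype vector must cover the same sites")
    eps = params.epsilon_for(H.shape[0])
    rho = params.rho_intervals(G.size)
    if method == "auto":
        method = "enumeration" if not np.any(rho) else "forward-backward"
    if method == "enumeration":
        if np.any(rho):
            raise ValueError("enumeration requires rho = 0 everywhere")
        missing, probs = _pair_enumeration_posterior(G, H, eps)
    elif method == "forward-backward":
        missing, probs = _forward_backward_posterior(G, H, eps, rho)
    else:
        raise ValueError(f"unknown method {method!r}")
    if ref_freq is None:
        ref_freq = H.mean(axis=0)[missing]
    best = call_genotypes(probs, np.asarray(ref_freq, dtype=float))
    return missing, probs, best


# ----------------------------------------------------------------------
def impute_cohort_hmm(cohort: Cohort, params: HMMParams | None = None) -> GenotypePosterior:
    """Impute all masked genotypes of all study individuals with the
    rho = 0 copying model, vectorised over individuals.

    Measured genotypes are taken from the study individuals' haplotype
    pairs (pre-phased usage); masked sites are treated as missing and
    re-estimated from the reference panel.
    """
    params = HMMParams() if params is None else params
    rho = params.rho_intervals(cohort.haps.n_sites)
    if np.any(rho):
        raise ValueError("cohort-level baseline supports only rho = 0; use impute_diploid")
    H_ref = cohort.haps.alleles[cohort.reference_ids].astype(np.float64)
    N = H_ref.shape[0]
    eps = params.epsilon_for(N)
    meas = cohort.measured_idx
    masked = cohort.masked_idx
    G_meas = cohort.genotypes(cohort.study_pairs, meas)  # (n_ind, n_meas)
    n_ind = G_meas.shape[0]

    # log emission matrices per measured site for each genotype value
    p_meas = H_ref[:, meas] * (1 - eps) + (1 - H_ref[:, meas]) * eps
    log_emit = np.empty((meas.size, 3, N, N))
    for j in range(meas.size):
        for g in (0, 1, 2):
            log_emit[j, g] = np.log(_emit_one(p_meas[:, j], g))

    p_mask = H_ref[:, masked] * (1 - eps) + (1 - H_ref[:, masked]) * eps  # (N, n_masked)
    ref_freq = cohort.haps.alleles[np.ix_(cohort.reference_ids, masked)].mean(axis=0)

    probs = np.empty((n_ind, masked.size, 3))
    best = np.empty((n_ind, masked.size), dtype=np.int8)
    chunk = max(1, int(2e8 // (8 * N * N)))
    for start in range(0, n_ind, chunk):
        stop = min(start + chunk, n_ind)
        logw = np.zeros((stop - start, N, N))
        for j in range(meas.size):
            logw += log_emit[j, G_meas[start:stop, j]]
        logw -= logw.max(axis=(1, 2), keepdims=True)
        w = np.exp(logw)
        w /= w.sum(axis=(1, 2), keepdims=True)
        # bilinear forms: P(G=2) = p' W p, P(G=0) = (1-p)' W (1-p)
        wp = np.matmul(w, p_mask)  # (c, N, n_masked)
        q2 = np.einsum("cnm,nm->cm", wp, p_mask)
        wq = np.matmul(w, 1.0 - p_mask)
        q0 = np.einsum("cnm,nm->cm", wq, 1.0 - p_mask)
        q1 = np.clip(1.0 - q0 - q2, 0.0, 1.0)
        block = np.stack([q0, q1, q2], axis=-1)
        block /= block.sum(axis=-1, keepdims=True)
        probs[start:stop] = block
        best[start:stop] = call_genotypes(block, ref_freq)
    return GenotypePosterior(
        pairs=cohort.study_pairs.copy(),
        masked_idx=masked.copy(),
        probs=probs,
        best_guess=best,
    )
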