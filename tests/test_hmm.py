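"""rho = 0 haplotype-copying HMM: emissions, oracles, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coalimpute import SimConfig, emission_prob, impute_diploid, simulate_cohort
from coalimpute.hmm import (
    HMMParams,
    _forward_backward_posterior,
    _pair_enumeration_posterior,
    impute_cohort_hmm,
    li_stephens_epsilon,
)


def test_emission_examples():
    assert emission_prob(2, (1, 1), 0.0) == 1.0
    assert emission_prob(0, (1, 1), 0.0) == 0.0
    eps = 0.1
    assert emission_prob(1, (1, 0), eps) == pytest.approx((1 - eps) ** 2 + eps**2)
    assert emission_prob(None, (1, 0), eps) == 1.0
    assert emission_prob(-1, (0, 0), eps) == 1.0
    with pytest.raises(ValueError):
        emission_prob(3, (1, 0), eps)
    with pytest.raises(ValueError):
        emission_prob(1, (2, 0), eps)


@settings(derandomize=True, max_examples=100)
@given(
    st.integers(0, 1), st.integers(0, 1),
    st.floats(0.0, 0.49, allow_nan=False),
)
def test_emission_normalises(a1, a2, eps):
    total = sum(emission_prob(g, (a1, a2), eps) for g in (0, 1, 2))
    assert total == pytest.approx(1.0)


def test_single_reference_copies_homozygote():
    H = np.array([[1, 0, 1, 0]], dtype=np.uint8)
    G = np.array([2, 0, -1, -1], dtype=np.int8)
    missing, probs, best = impute_diploid(G, H, HMMParams(miscopy_epsilon=1e-9))
    assert missing.tolist() == [2, 3]
    assert best.tolist() == [2 * 1, 2 * 0]
    assert probs[0, 2] == pytest.approx(1.0, abs=1e-6)


def test_true_pair_in_panel_recovers_truth():
    """When the individual's two true haplotypes are in the panel and no
    other pair reproduces the measured genotypes, the dominant copying
    pair makes the best guess exact at every masked site."""
    H = np.array([
        [0, 0, 1, 0, 1],
        [1, 1, 0, 0, 1],
        [0, 1, 1, 1, 0],
    ], dtype=np.uint8)
    truth = H[0].astype(np.int8) + H[1].astype(np.int8)  # pair (0, 1)
    G = truth.copy()
    G[[3, 4]] = -1  # mask the last two sites
    # (0,1) is the only ordered pair matching genotypes (1,1,1) at the
    # observed sites, so with tiny epsilon it dominates the posterior
    missing, probs, best = impute_diploid(G, H, HMMParams(miscopy_epsilon=1e-6))
    assert missing.tolist() == [3, 4]
    assert best.tolist() == truth[[3, 4]].tolist()


def _brute_force(G, H, eps):
    """Triple-loop enumeration over ordered pairs using emission_prob."""
    N, L = H.shape
    w = np.zeros((N, N))
    for z1 in range(N):
        for z2 in range(N):
            p = 1.0
            for j in range(L):
                g = None if G[j] < 0 else int(G[j])
                p *= emission_prob(g, (int(H[z1, j]), int(H[z2, j])), eps)
            w[z1, z2] = p
    w /= w.sum()
    missing = np.flatnonzero(G < 0)
    probs = np.empty((missing.size, 3))
    for k, j in enumerate(missing):
        for g in (0, 1, 2):
            probs[k, g] = sum(
                w[z1, z2] * emission_prob(g, (int(H[z1, j]), int(H[z2, j])), eps)
                for z1 in range(N) for z2 in range(N)
            )
    return probs


def test_posterior_matches_brute_force_enumeration():
    rng = np.random.default_rng(3)
    for _ in range(5):
        N, L = int(rng.integers(2, 6)), int(rng.integers(3, 7))
        H = rng.integers(0, 2, size=(N, L)).astype(np.uint8)
        G = rng.integers(0, 3, size=L).astype(np.int8)
        G[rng.choice(L, size=2, replace=False)] = -1
        eps = float(rng.uniform(0.01, 0.3))
        _, probs, _ = impute_diploid(G, H, HMMParams(miscopy_epsilon=eps),
                                     method="enumeration")
        brute = _brute_force(G, H, eps)
        np.testing.assert_allclose(probs, brute, atol=1e-12)


def test_forward_backward_equals_enumeration_at_rho_zero():
    """Two code paths, one answer when the copying pair cannot switch."""
    rng = np.random.default_rng(4)
    for _ in range(4):
        N, L = int(rng.integers(2, 6)), int(rng.integers(3, 7))
        H = rng.integers(0, 2, size=(N, L)).astype(np.float64)
        G = rng.integers(0, 3, size=L).astype(np.int8)
        G[rng.choice(L, size=2, replace=False)] = -1
        eps = float(rng.uniform(0.01, 0.3))
        m1, p1 = _pair_enumeration_posterior(G, H, eps)
        m2, p2 = _forward_backward_posterior(G, H, eps, np.zeros(L - 1))
        assert np.array_equal(m1, m2)
        np.testing.assert_allclose(p1, p2, atol=1e-10)


def test_rho_zero_invariant_to_site_order():
    rng = np.random.default_rng(5)
    N, L = 5, 8
    H = rng.integers(0, 2, size=(N, L)).astype(np.uint8)
    G = rng.integers(0, 3, size=L).astype(np.int8)
    G[[1, 4]] = -1
    perm = rng.permutation(L)
    _, probs, _ = impute_diploid(G, H, HMMParams(miscopy_epsilon=0.05))
    _, probs_p, _ = impute_diploid(G[perm], H[:, perm], HMMParams(miscopy_epsilon=0.05))
    # compare probabilities site by site via original indices
    orig_sites = perm[np.flatnonzero(G[perm] < 0)]
    lookup = {int(s): k for k, s in enumerate(np.flatnonzero(G < 0))}
    for k, s in enumerate(orig_sites):
        np.testing.assert_allclose(probs_p[k], probs[lookup[int(s)]], atol=1e-12)


def test_cohort_hmm_matches_per_individual_path():
    """The vectorised cohort routine agrees with impute_diploid."""
    cohort = simulate_cohort(SimConfig(n_haplotypes=30, n_sites_S=20, seed_sim=6))
    post = impute_cohort_hmm(cohort)
    H = cohort.haps.alleles[cohort.reference_ids]
    for i in [0, 3]:
        a, b = cohort.study_pairs[i]
        G = cohort.haps.alleles[a].astype(np.int8) + cohort.haps.alleles[b].astype(np.int8)
        G[cohort.masked_idx] = -1
        _, probs, best = impute_diploid(G, H)
        np.testing.assert_allclose(post.probs[i], probs, atol=1e-9)
        assert np.array_equal(post.best_guess[i], best)
    assert np.allclose(post.probs.sum(axis=2), 1.0)


def test_epsilon_default_and_validation():
    # N-dependent Li-Stephens value: theta~/(2(theta~+N))
    n = 200
    theta = 1.0 / np.sum(1.0 / np.arange(1, n))
    assert li_stephens_epsilon(n) == pytest.approx(theta / (2 * (theta + n)))
    with pytest.raises(ValueError):
        HMMParams(miscopy_epsilon=0.7).epsilon_for(10)
    with pytest.raises(ValueError):
        impute_diploid(np.array([0, 1]), np.empty((0, 2)))
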