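"""Perfect phylogeny, coalescent prior and infinite-sites likelihood."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coalimpute import (
    DemographyModel,
    GeneTree,
    IncompatibleSitesError,
    build_perfect_phylogeny,
    coalescent_log_prior,
    four_gamete_compatible,
    infinite_sites_loglik,
    overlay_mutations,
    sample_genealogy,
)


# ----------------------------------------------------------------------
def test_four_gamete_examples():
    assert not four_gamete_compatible([0, 0, 1, 1], [0, 1, 0, 1])
    assert four_gamete_compatible([0, 0, 1, 1], [0, 0, 0, 1])
    col = np.array([0, 1, 1, 0])
    assert four_gamete_compatible(col, col)
    with pytest.raises(ValueError):
        four_gamete_compatible([0, 1], [0, 1, 1])


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=2, max_size=12))
def test_four_gamete_matches_enumeration(pairs):
    a = np.array([p[0] for p in pairs])
    b = np.array([p[1] for p in pairs])
    gametes = {(x, y) for x, y in pairs}
    assert four_gamete_compatible(a, b) == (len(gametes) < 4)


# ----------------------------------------------------------------------
def _clades(tree: GeneTree):
    packed = tree.leaf_masks_packed()
    return {
        frozenset(np.flatnonzero(np.unpackbits(packed[i])[: tree.n_leaves]).tolist())
        for i in range(tree.n_leaves, tree.n_nodes)
    }


def test_perfect_phylogeny_nested_chain():
    # carriers {1,2} and {1,2,3} over haplotypes 0..3 force a nested chain
    alleles = np.zeros((4, 2), dtype=np.uint8)
    alleles[[1, 2], 0] = 1
    alleles[[1, 2, 3], 1] = 1
    tree = build_perfect_phylogeny(alleles)
    assert _clades(tree) == {frozenset({1, 2}), frozenset({1, 2, 3}), frozenset({0, 1, 2, 3})}


def test_perfect_phylogeny_singletons_give_star():
    alleles = np.eye(5, dtype=np.uint8)[:, :3]
    tree = build_perfect_phylogeny(alleles)
    assert _clades(tree) == {frozenset(range(5))}


def test_perfect_phylogeny_incompatible_error():
    alleles = np.zeros((4, 2), dtype=np.uint8)
    alleles[[0, 1], 0] = 1
    alleles[[1, 2], 1] = 1
    with pytest.raises(IncompatibleSitesError) as err:
        build_perfect_phylogeny(alleles)
    assert err.value.site_pair == (0, 1)


# ----------------------------------------------------------------------
def _two_leaf_tree(t):
    return GeneTree([2, 2, -1], [0.0, 0.0, t], 2)


def _three_leaf_tree(t1, t2):
    # (0,1) coalesce at t1, root at t2
    return GeneTree([3, 3, 4, 4, -1], [0.0, 0.0, 0.0, t1, t2], 3)


def test_coalescent_log_prior_constant_size():
    assert coalescent_log_prior(_two_leaf_tree(0.7)) == pytest.approx(-0.7)
    t1, t2 = 0.2, 0.9
    expected = (np.log(3) - 3 * t1) - (t2 - t1)
    assert coalescent_log_prior(_three_leaf_tree(t1, t2)) == pytest.approx(expected)


def test_coalescent_log_prior_growth_favors_short_trees():
    """For a tree shorter than the onset epoch the growth-rescaled density
    increases with the growth rate (the shrunken sizes raise the rate)."""
    tree = _three_leaf_tree(0.002, 0.006)
    lps = [
        coalescent_log_prior(tree, DemographyModel(growth_rate_alpha=a,
                                                   growth_onset_generations=200))
        for a in (0.0, 0.0125, 0.05)
    ]
    assert lps[0] < lps[1] < lps[2]


def test_coalescent_log_prior_structure_split_constraint():
    dem = DemographyModel(n_subpops_beta=2, split_time_generations=2000)
    t_split = dem.split_internal
    # leaves 0,1 in deme 0 and 2,3 in deme 1; root merges the demes
    def tree_with_root(t_root):
        parent = [4, 4, 5, 5, 6, 6, -1]
        time = [0, 0, 0, 0, 0.01, 0.02, t_root]
        return GeneTree(parent, time, 4, demes=[0, 0, 1, 1])

    assert np.isfinite(coalescent_log_prior(tree_with_root(t_split * 2), dem))
    assert coalescent_log_prior(tree_with_root(t_split / 2), dem) == -np.inf


def test_coalescent_log_prior_rejects_bad_trees():
    tree = GeneTree([2, 2, -1], [0.0, 0.0, np.nan], 2)
    with pytest.raises(ValueError):
        coalescent_log_prior(tree)


# ----------------------------------------------------------------------
def test_infinite_sites_two_leaf_placement_factor():
    """One site on a two-leaf tree: the placement factor is log(1/2)."""
    tree = _two_leaf_tree(1.0)  # both branches length 1, T = 2
    alleles = np.array([[1], [0]], dtype=np.uint8)
    theta = 3.0
    T = 2.0
    poisson_part = np.log(theta * T / 2) - theta * T / 2
    ll = infinite_sites_loglik(tree, alleles, theta)
    assert ll - poisson_part == pytest.approx(np.log(0.5))


def test_infinite_sites_incompatible_is_minus_inf():
    tree = _three_leaf_tree(0.3, 1.0)
    bad = np.array([[1], [0], [1]], dtype=np.uint8)  # {0,2} is not a clade
    assert infinite_sites_loglik(tree, bad, 2.0) == -np.inf


def _brute_force_likelihood(tree: GeneTree, alleles, theta):
    """Sum over every assignment of sites to branches."""
    from scipy.special import gammaln

    b = tree.branch_lengths()
    T = b.sum()
    packed = tree.leaf_masks_packed()
    n, S = alleles.shape
    patterns = [
        np.unpackbits(packed[node])[:n].astype(np.uint8) for node in range(tree.n_nodes)
    ]
    branches = [i for i in range(tree.n_nodes) if b[i] > 0]
    poisson = np.exp(S * np.log(theta * T / 2) - theta * T / 2 - gammaln(S + 1))
    total = 0.0
    for assign in itertools.product(branches, repeat=S):
        if all(np.array_equal(patterns[assign[s]], alleles[:, s]) for s in range(S)):
            total += np.prod([b[i] / T for i in assign])
    return poisson * total


def test_infinite_sites_matches_brute_force_placement():
    rng = np.random.default_rng(17)
    for _ in range(6):
        tree = sample_genealogy(rng.integers(3, 6), rng=rng)
        S = int(rng.integers(1, 5))
        haps = overlay_mutations(tree, S, 1000, rng)
        theta = float(rng.uniform(0.5, 5))
        ll = infinite_sites_loglik(tree, haps.alleles, theta)
        brute = _brute_force_likelihood(tree, haps.alleles, theta)
        assert np.exp(ll) == pytest.approx(brute, rel=1e-9)
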