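"""Simulator: coalescent genealogies, infinite-sites mutations, cohorts."""

import numpy as np
import pytest
from scipy import stats

from coalimpute import (
    DemographyModel,
    SimConfig,
    choose_measured_sites,
    four_gamete_compatible,
    make_cohort,
    overlay_mutations,
    sample_genealogy,
    simulate_cohort,
)
from coalimpute.simulate import HaplotypeMatrix


# ----------------------------------------------------------------------
@pytest.mark.parametrize(
    "n, expected, n_rep, tol",
    [(2, 1.0, 20_000, 0.03), (10, 2 * (1 - 1 / 10), 6_000, 0.05)],
)
def test_mean_tmrca_matches_closed_form(n, expected, n_rep, tol):
    """E[TMRCA] = 2(1 - 1/n) coalescent units for a constant population."""
    rng = np.random.default_rng(12345)
    mean = np.mean([sample_genealogy(n, rng=rng).tmrca for _ in range(n_rep)])
    assert abs(mean - expected) < tol


def test_growth_shortens_tmrca():
    """Backward-shrinking population sizes compress coalescence times."""
    rng = np.random.default_rng(7)
    dem = DemographyModel(growth_rate_alpha=0.05, growth_onset_generations=200)
    with_growth = np.mean([sample_genealogy(10, dem, rng).tmrca for _ in range(1_500)])
    constant = np.mean([sample_genealogy(10, rng=rng).tmrca for _ in range(1_500)])
    assert with_growth < constant
    # all residual lineages coalesce quickly once the tiny ancestral size
    # is reached, so the TMRCA sits near the growth-onset epoch
    assert with_growth < 0.05


def test_intercoalescence_intervals_are_exponential():
    """With k lineages the waiting time is Exponential(k(k-1)/2)."""
    rng = np.random.default_rng(99)
    n = 8
    intervals = {k: [] for k in range(2, n + 1)}
    for _ in range(2_500):
        tree = sample_genealogy(n, rng=rng)
        times = np.sort(tree.time[n:])
        bounds = np.concatenate([[0.0], times])
        for j, k in enumerate(range(n, 1, -1)):
            intervals[k].append(bounds[j + 1] - bounds[j])
    for k, vals in intervals.items():
        rate = k * (k - 1) / 2
        p = stats.kstest(np.asarray(vals) * rate, "expon").pvalue
        assert p > 0.005, f"interval distribution for k={k} rejects Exp (p={p:.2g})"


def test_structure_no_cross_deme_coalescence_before_split():
    rng = np.random.default_rng(3)
    dem = DemographyModel(n_subpops_beta=3, split_time_generations=2000)
    t_split = dem.split_internal
    for _ in range(40):
        tree = sample_genealogy(12, dem, rng)
        packed = tree.leaf_masks_packed()
        for node in range(tree.n_leaves, tree.n_nodes):
            if tree.time[node] < t_split:
                leaves = np.flatnonzero(np.unpackbits(packed[node])[: tree.n_leaves])
                assert len(set(tree.demes[leaves])) == 1


def test_site_frequency_spectrum_proportional_to_inverse_count():
    """Poisson-rate mutation counts give E[#sites at derived count i] ~ 1/i."""
    rng = np.random.default_rng(11)
    n = 6
    counts = np.zeros(n - 1)
    for _ in range(4_000):
        tree = sample_genealogy(n, rng=rng)
        s = rng.poisson(1.0 * tree.total_length)
        if s == 0:
            continue
        haps = overlay_mutations(tree, s, 100_000, rng)
        freq = haps.alleles.sum(axis=0)
        for f in freq:
            counts[f - 1] += 1
    expected = 1.0 / np.arange(1, n)
    expected = expected / expected.sum() * counts.sum()
    p = stats.chisquare(counts, expected).pvalue
    assert p > 0.001, f"SFS deviates from 1/i (p={p:.2g}, counts={counts})"


def test_cross_check_against_msprime():
    """Independent simulator agrees on the mean TMRCA under growth."""
    import msprime

    alpha, onset_gen, n_e, n = 0.01, 400.0, 10_000, 20
    rng = np.random.default_rng(21)
    dem = DemographyModel(n_e=n_e, growth_rate_alpha=alpha, growth_onset_generations=onset_gen)
    ours = np.mean([sample_genealogy(n, dem, rng).tmrca for _ in range(800)])

    # msprime with ploidy=1 counts haploid gene copies, so a diploid
    # population of size N_e corresponds to 2*N_e copies
    demog = msprime.Demography()
    demog.add_population(initial_size=2 * n_e, growth_rate=alpha)
    demog.add_population_parameters_change(
        time=onset_gen, growth_rate=0.0, initial_size=2 * n_e * np.exp(-alpha * onset_gen)
    )
    reps = msprime.sim_ancestry(
        samples={"pop_0": n}, ploidy=1, demography=demog,
        num_replicates=800, random_seed=42,
    )
    theirs = np.mean([ts.max_root_time for ts in reps]) / (2 * n_e)
    assert abs(ours - theirs) < 0.1 * theirs


# ----------------------------------------------------------------------
def test_overlay_mutations_properties():
    rng = np.random.default_rng(5)
    tree = sample_genealogy(20, rng=rng)
    haps = overlay_mutations(tree, 100, 20_000, rng)
    assert haps.alleles.shape == (20, 100)
    assert haps.is_polymorphic().all()
    assert np.all(np.diff(haps.positions) > 0)
    assert haps.positions[0] >= 1 and haps.positions[-1] <= 20_000
    # each column's carrier set is a clade of the generating tree
    packed = tree.leaf_masks_packed()
    clades = {packed[node].tobytes() for node in range(tree.n_nodes)}
    for j in range(haps.n_sites):
        key = np.packbits(haps.alleles[:, j].astype(bool)).tobytes()
        assert key in clades


def test_two_leaf_tree_single_site():
    rng = np.random.default_rng(6)
    tree = sample_genealogy(2, rng=rng)
    haps = overlay_mutations(tree, 1, 100, rng)
    assert haps.alleles.sum() == 1


def test_simulated_matrices_are_four_gamete_compatible():
    """Single-tree (no recombination) data never violates the screen."""
    for seed in range(3):
        cohort = simulate_cohort(SimConfig(n_haplotypes=30, n_sites_S=15, seed_sim=seed))
        a = cohort.haps.alleles
        for i in range(a.shape[1]):
            for j in range(i + 1, a.shape[1]):
                assert four_gamete_compatible(a[:, i], a[:, j])


# ----------------------------------------------------------------------
@pytest.mark.parametrize("n, n_study, n_ref", [(1000, 800, 200), (200, 160, 40)])
def test_make_cohort_split_sizes(n, n_study, n_ref):
    cohort = simulate_cohort(SimConfig(n_haplotypes=n, n_sites_S=20))
    assert cohort.study_ids.size == n_study
    assert cohort.reference_ids.size == n_ref
    assert cohort.study_pairs.shape == (n_study // 2, 2)


def test_make_cohort_deterministic():
    a = simulate_cohort(SimConfig(n_haplotypes=100, n_sites_S=20, seed_sim=4, seed_sites=9))
    b = simulate_cohort(SimConfig(n_haplotypes=100, n_sites_S=20, seed_sim=4, seed_sites=9))
    assert np.array_equal(a.haps.alleles, b.haps.alleles)
    assert np.array_equal(a.study_ids, b.study_ids)
    assert np.array_equal(a.study_pairs, b.study_pairs)
    assert np.array_equal(a.measured_idx, b.measured_idx)


def test_make_cohort_rejects_odd_partitions():
    rng = np.random.default_rng(0)
    tree = sample_genealogy(10, rng=rng)
    haps = overlay_mutations(tree, 5, 1000, rng)
    with pytest.raises(ValueError, match="even"):
        make_cohort(haps, SimConfig(n_haplotypes=10, n_sites_S=5, study_fraction=0.5), rng)


def test_choose_measured_sites_counts():
    rng = np.random.default_rng(1)
    tree = sample_genealogy(30, rng=rng)
    haps = overlay_mutations(tree, 100, 20_000, rng)
    assert choose_measured_sites(haps, 0.1, rng=rng).size == 10
    assert np.array_equal(
        choose_measured_sites(haps, 1.0, rng=rng), np.arange(100)
    )
    # no recombination: the compatible subset is every site
    assert np.array_equal(
        choose_measured_sites(haps, 1.0, compatible_only=True, rng=rng), np.arange(100)
    )


def test_choose_measured_sites_too_few_eligible():
    # two incompatible columns: the greedy screen keeps only the first
    alleles = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.uint8)
    haps = HaplotypeMatrix(ids=list("abcd"), positions=[1, 2], alleles=alleles)
    with pytest.raises(ValueError, match="eligible"):
        choose_measured_sites(haps, 1.0, compatible_only=True,
                              rng=np.random.default_rng(0))


# ----------------------------------------------------------------------
def test_demography_validation():
    with pytest.raises(ValueError):
        DemographyModel(n_e=-1).validate()
    with pytest.raises(ValueError):
        DemographyModel(growth_rate_alpha=-0.1).validate()
    with pytest.raises(ValueError):
        DemographyModel(n_subpops_beta=2, split_time_generations=0).validate()
    with pytest.raises(ValueError):
        sample_genealogy(1)
    dem = DemographyModel(n_subpops_beta=3)
    with pytest.raises(ValueError, match="divisible"):
        sample_genealogy(10, dem, np.random.default_rng(0))


def test_year_based_epoch_conversion():
    dem = DemographyModel(generation_time_years=25.0)
    assert dem.years_to_internal(5_000) == pytest.approx(200 / 20_000)
    assert dem.years_to_internal(50_000) == pytest.approx(2000 / 20_000)
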