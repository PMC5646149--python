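"""Template selection and coalescent-based imputation."""

import numpy as np
import pytest

from coalimpute import (
    GeneTree,
    TemplateRule,
    annotate_clade_times,
    coalescence_time,
    find_templates,
    impute_cohort,
    impute_haplotype,
    impute_individual,
    majority_consensus,
    mcmc_sample,
)
from coalimpute.impute import call_genotypes
from coalimpute.simulate import Cohort, HaplotypeMatrix


def _consensus_of(tree):
    return annotate_clade_times(majority_consensus([tree]), [tree])


# ----------------------------------------------------------------------
def test_coalescence_time_lookup_and_symmetry():
    # cherry (0,1) at 0.3, root at 1.2 over 4 leaves
    tree = GeneTree([4, 4, 5, 6, 5, 6, -1], [0, 0, 0, 0, 0.3, 0.8, 1.2], 4)
    cons = _consensus_of(tree)
    assert coalescence_time(cons, 0, 1) == pytest.approx(0.3)
    assert coalescence_time(cons, 0, 3) == pytest.approx(1.2)
    rng = np.random.default_rng(0)
    for _ in range(10):
        a, b = rng.choice(4, 2, replace=False)
        assert coalescence_time(cons, int(a), int(b)) == coalescence_time(cons, int(b), int(a))
    with pytest.raises(ValueError):
        coalescence_time(cons, 0, 9)


# ----------------------------------------------------------------------
def test_cohort_invariants_reject_partial_pairing():
    alleles = np.array([[0, 1], [1, 0], [0, 0], [1, 1]], dtype=np.uint8)
    haps = HaplotypeMatrix(ids=list("abcd"), positions=[1, 2], alleles=alleles)
    with pytest.raises(ValueError, match="pairing"):
        Cohort(
            haps=haps,
            study_ids=np.array([0, 1]),
            reference_ids=np.array([2, 3]),
            study_pairs=np.array([[0, 1]]),
            reference_pairs=np.empty((0, 2), dtype=int),
            measured_idx=np.array([0]),
            masked_idx=np.array([1]),
        )


def _window_cohort():
    """Study haplotype 0 (unique at measured sites) with references 2, 3
    on a caterpillar whose TMRCAs with 0 are 0.50 and 0.60."""
    tree = GeneTree([4, 4, 5, 6, 5, 6, -1], [0, 0, 0, 0, 0.10, 0.50, 0.60], 4)
    alleles = np.array([
        [1, 1, 0, 0],   # hap 0 (study, unique at measured sites)
        [0, 1, 0, 1],   # hap 1 (study partner filler)
        [0, 0, 0, 1],   # hap 2 (reference)
        [0, 0, 1, 0],   # hap 3 (reference)
    ], dtype=np.uint8)
    # make 1 a study haplotype so the reference panel is {2, 3}
    haps = HaplotypeMatrix(ids=[f"hap_{i}" for i in range(4)],
                           positions=[10, 20, 30, 40], alleles=alleles)
    cohort = Cohort(
        haps=haps,
        study_ids=np.array([0, 1]),
        reference_ids=np.array([2, 3]),
        study_pairs=np.array([[0, 1]]),
        reference_pairs=np.array([[2, 3]]),
        measured_idx=np.array([0, 1]),
        masked_idx=np.array([2, 3]),
    )
    return tree, cohort


def test_find_templates_first_coalescing_only():
    """With a tight window only the first-coalescing reference is kept."""
    tree, cohort = _window_cohort()
    cons = _consensus_of(tree)
    # TMRCA(0, 2) = 0.50; TMRCA(0, 3) = 0.60
    templates = find_templates(0, cohort, cons, TemplateRule(delta_generations=0.0))
    assert templates.tolist() == [2]


def test_find_templates_window_boundary():
    """References within t* + delta all serve as templates."""
    tree, cohort = _window_cohort()
    cons = _consensus_of(tree)
    # delta = 0.1 internal units -> 0.1 * 2 * n_e generations with n_e=1
    rule = TemplateRule(delta_generations=0.2, n_e=1.0)  # delta_internal = 0.1
    templates = find_templates(0, cohort, cons, rule)
    assert templates.tolist() == [2, 3]


def test_find_templates_identical_matches_take_precedence():
    tree, cohort = _window_cohort()
    cons = _consensus_of(tree)
    # make both references identical to study hap 0 at measured sites
    cohort.haps.alleles[2, [0, 1]] = [1, 1]
    cohort.haps.alleles[3, [0, 1]] = [1, 1]
    templates = find_templates(0, cohort, cons, TemplateRule(delta_generations=0.0))
    assert templates.tolist() == [2, 3]


def test_find_templates_empty_panel():
    tree, cohort = _window_cohort()
    cons = _consensus_of(tree)
    import dataclasses
    with pytest.raises(ValueError):
        bad = dataclasses.replace(
            cohort,
            study_ids=np.arange(4),
            reference_ids=np.array([], dtype=int),
            study_pairs=np.array([[0, 1], [2, 3]]),
            reference_pairs=np.empty((0, 2), dtype=int),
        )
        find_templates(0, bad, cons, TemplateRule())


# ----------------------------------------------------------------------
def test_impute_haplotype_template_frequencies():
    _, cohort = _window_cohort()
    # masked sites are s2, s3; haps 2 and 3 carry (0,1) and (1,0)
    assert impute_haplotype(np.array([2]), cohort).tolist() == [0.0, 1.0]
    assert impute_haplotype(np.array([2, 3]), cohort).tolist() == [0.5, 0.5]
    with pytest.raises(ValueError):
        impute_haplotype(np.array([], dtype=int), cohort)


def test_impute_individual_combination_rule():
    probs, best = impute_individual([1.0], [1.0])
    assert probs[0].tolist() == [0.0, 0.0, 1.0] and best[0] == 2
    probs, best = impute_individual([1.0], [0.0])
    assert probs[0].tolist() == [0.0, 1.0, 0.0] and best[0] == 1
    probs, best = impute_individual([0.5], [0.5])
    assert probs[0].tolist() == [0.25, 0.5, 0.25] and best[0] == 1
    with pytest.raises(ValueError):
        impute_individual([0.5], [0.5, 0.5])


def test_tie_break_follows_reference_frequency():
    # exact tie between genotypes 0 and 1; rare allele -> call 0
    probs = np.array([[0.5, 0.5, 0.0]])
    assert call_genotypes(probs, np.array([0.05]))[0] == 0
    # common allele (freq 0.5) -> heterozygote has the larger HWE mass
    assert call_genotypes(probs, np.array([0.5]))[0] == 1


# ----------------------------------------------------------------------
def test_toy_cohort_end_to_end_perfect(toy_cohort):
    """No-noise perfect-phylogeny cohort: imputed best guesses equal the
    held-out truth through the full MCMC -> consensus -> imputation path."""
    sample = mcmc_sample(
        toy_cohort.haps.alleles[:, toy_cohort.measured_idx],
        n_samples=100, thinning=2, rng=np.random.default_rng(5),
    )
    cons = annotate_clade_times(majority_consensus(sample), sample)
    post = impute_cohort(toy_cohort, cons)
    truth = toy_cohort.study_truth()
    assert np.array_equal(post.best_guess, truth)
    assert np.allclose(post.probs.sum(axis=2), 1.0)


def test_identical_study_signatures_share_allele_probs(toy_cohort):
    sample = mcmc_sample(
        toy_cohort.haps.alleles[:, toy_cohort.measured_idx],
        n_samples=60, thinning=2, rng=np.random.default_rng(6),
    )
    cons = annotate_clade_times(majority_consensus(sample), sample)
    post = impute_cohort(toy_cohort, cons)
    # study haplotype 0 and reference 1 share a group; imputing twice with
    # permuted template order cannot change the frequencies
    assert post.hap_allele_probs is not None
    assert np.all((post.hap_allele_probs >= 0) & (post.hap_allele_probs <= 1))


def test_true_donor_gives_perfect_haplotype(toy_cohort):
    """A unique identical-at-measured-sites donor that matches at every
    site yields error-free imputation for that haplotype."""
    sample = mcmc_sample(
        toy_cohort.haps.alleles[:, toy_cohort.measured_idx],
        n_samples=60, thinning=2, rng=np.random.default_rng(7),
    )
    cons = annotate_clade_times(majority_consensus(sample), sample)
    templates = find_templates(0, toy_cohort, cons)
    assert templates.tolist() == [1]  # the donor
    p = impute_haplotype(templates, toy_cohort)
    truth = toy_cohort.haps.alleles[0, toy_cohort.masked_idx]
    assert np.array_equal(p.astype(np.uint8), truth)
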