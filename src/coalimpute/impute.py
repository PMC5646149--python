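"""Coalescent-based genotype imputation from an annotated consensus tree.

For each study haplotype the imputation templates are (1) all reference
haplotypes identical to it at the directly measured sites, or, failing
that, (2) every reference haplotype whose TMRCA with the study haplotype
(mean posterior coalescence time on the consensus tree) lies within a
small co-coalescence window ``delta`` of the first-coalescing reference
haplotype.  Masked-site allele probabilities are the allele frequencies
among the selected templates; the two haplotypes of a diploid individual
are combined independently into genotype probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .consensus import ConsensusTree
from .simulate import Cohort

__all__ = [
    "TemplateRule",
    "GenotypePosterior",
    "coalescence_time",
    "find_templates",
    "impute_haplotype",
    "impute_individual",
    "impute_cohort",
    "call_genotypes",
]


@dataclass(frozen=True)
class TemplateRule:
    """Co-coalescence window for template selection.

    Reference haplotypes whose TMRCA with the study haplotype is within
    ``delta_generations`` (converted to coalescent units via ``2 * n_e``)
    of the minimum TMRCA all serve as templates.  The default of 10
    generations corresponds to 0.0005 units at ``n_e`` = 10,000.
    """

    delta_generations: float = 10.0
    n_e: float = 10_000.0

    def __post_init__(self):
        if self.delta_generations < 0:
            raise ValueError("delta_generations must be >= 0")
        if self.n_e <= 0:
            raise ValueError("n_e must be positive")

    @property
    def delta_internal(self) -> float:
        return self.delta_generations / (2.0 * self.n_e)


@dataclass
class GenotypePosterior:
    """Per-individual, per-masked-site genotype probabilities.

    ``probs[i, j, g]`` is the probability that study individual ``i``
    carries ``g`` copies of the derived allele at masked site ``j``
    (columns follow ``masked_idx``); ``best_guess`` is the argmax call
    with frequency-consistent tie-breaking.  ``hap_allele_probs`` holds
    the per-haplotype derived-allele probabilities (rows follow
    ``hap_ids``) where the method produces them (the coalescent imputer
    does, the genotype-copying HMM does not).
    """

    pairs: np.ndarray  # (n_individuals, 2) haplotype indices
    masked_idx: np.ndarray
    probs: np.ndarray  # (n_individuals, n_masked, 3)
    best_guess: np.ndarray  # (n_individuals, n_masked) in {0,1,2}
    hap_ids: np.ndarray | None = None
    hap_allele_probs: np.ndarray | None = None

    def __post_init__(self):
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("genotype probabilities must sum to 1")


# ----------------------------------------------------------------------
def coalescence_time(consensus: ConsensusTree, leaf_a: int, leaf_b: int) -> float:
    """Mean posterior TMRCA of two leaves on an annotated consensus tree:
    the mean time of the smallest retained clade containing both."""
    if np.any(np.isnan(consensus.mean_time)):
        raise ValueError("consensus tree has no time annotation; run annotate_clade_times")
    return float(consensus.mean_time[consensus.mrca_clade(leaf_a, leaf_b)])


def find_templates(
    study_hap: int,
    cohort: Cohort,
    consensus: ConsensusTree,
    rule: TemplateRule | None = None,
) -> np.ndarray:
    """Reference haplotypes serving as imputation templates for one study
    haplotype.

    Identical matches at the measured sites take precedence and the tree
    is not consulted; otherwise all reference haplotypes with TMRCA within
    ``rule.delta_internal`` of the minimum TMRCA are returned.
    """
    rule = TemplateRule() if rule is None else rule
    if cohort.reference_ids.size == 0:
        raise ValueError("reference panel is empty")
    measured = cohort.haps.alleles[:, cohort.measured_idx]
    target = measured[study_hap]
    identical = cohort.reference_ids[
        (measured[cohort.reference_ids] == target).all(axis=1)
    ]
    if identical.size:
        return identical
    return _window_templates(study_hap, cohort.reference_ids, consensus, rule)


def _window_templates(study_hap, reference_ids, consensus, rule):
    """First-coalescing reference haplotypes within the delta window."""
    if np.any(np.isnan(consensus.mean_time)):
        raise ValueError("consensus tree has no time annotation; run annotate_clade_times")
    ref_set = np.zeros(consensus.n_leaves, dtype=bool)
    ref_set[reference_ids] = True
    delta = rule.delta_internal
    node = int(consensus.leaf_attach[study_hap])
    seen = np.zeros(consensus.n_leaves, dtype=bool)
    seen[study_hap] = True
    t_star = None
    out: list[int] = []
    while node != -1:
        clade = consensus.clade_leafset(node)
        new = clade & ~seen
        seen |= clade
        t_node = float(consensus.mean_time[node])
        new_refs = np.flatnonzero(new & ref_set)
        if new_refs.size:
            if t_star is None:
                t_star = t_node
            if t_node <= t_star + delta:
                out.extend(new_refs.tolist())
        if t_star is not None and t_node > t_star + delta:
            break
        node = int(consensus.parent[node]) if node != 0 else -1
    return np.array(sorted(out), dtype=np.int64)


def impute_haplotype(templates: np.ndarray, cohort: Cohort) -> np.ndarray:
    """Per-masked-site derived-allele probability: the allele frequency
    among the selected templates."""
    templates = np.asarray(templates, dtype=np.int64)
    if templates.size == 0:
        raise ValueError("template set is empty")
    return cohort.haps.alleles[np.ix_(templates, cohort.masked_idx)].mean(axis=0)


def call_genotypes(probs: np.ndarray, ref_freq: np.ndarray) -> np.ndarray:
    """Best-guess genotypes: argmax with ties broken toward the genotype
    of higher Hardy-Weinberg probability at the reference-panel allele
    frequency (remaining ties toward the lower dosage)."""
    probs = np.asarray(probs, dtype=float)
    f = np.asarray(ref_freq, dtype=float)
    hwe = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1)
    top = probs.max(axis=-1, keepdims=True)
    is_top = probs >= top - 1e-12
    keyed = np.where(is_top, hwe, -1.0)
    return keyed.argmax(axis=-1).astype(np.int8)


def impute_individual(hap_probs_a, hap_probs_b, ref_freq=None):
    """Combine two haplotype imputations into genotype probabilities.

    Treats the haplotypes as independent: P(G=2) = p_a*p_b,
    P(G=0) = (1-p_a)(1-p_b), P(G=1) the remainder.  Returns
    ``(probs, best_guess)``; ``ref_freq`` feeds the tie-break (defaults to
    0.5 everywhere, i.e. ties resolve toward the heterozygote).
    """
    pa = np.asarray(hap_probs_a, dtype=float)
    pb = np.asarray(hap_probs_b, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("haplotype probability vectors must cover the same sites")
    p2 = pa * pb
    p0 = (1 - pa) * (1 - pb)
    p1 = 1.0 - p0 - p2
    probs = np.stack([p0, p1, p2], axis=-1)
    np.clip(probs, 0.0, 1.0, out=probs)
    if ref_freq is None:
        ref_freq = np.full(pa.shape, 0.5)
    return probs, call_genotypes(probs, ref_freq)


# ----------------------------------------------------------------------
def impute_cohort(
    cohort: Cohort,
    consensus: ConsensusTree,
    rule: TemplateRule | None = None,
) -> GenotypePosterior:
    """Impute all masked genotypes of all study individuals.

    Study haplotypes sharing a measured-site signature share templates, so
    template lookups are cached per signature.
    """
    rule = TemplateRule() if rule is None else rule
    ref_freq = cohort.haps.alleles[np.ix_(cohort.reference_ids, cohort.masked_idx)].mean(axis=0)
    measured = cohort.haps.alleles[:, cohort.measured_idx]
    cache: dict[bytes, np.ndarray] = {}
    n_masked = cohort.masked_idx.size

    study_order = {int(h): i for i, h in enumerate(cohort.study_ids)}
    hap_probs = np.empty((cohort.study_ids.size, n_masked))
    for h in cohort.study_ids:
        key = measured[h].tobytes()
        if key in cache:
            p = cache[key]
        else:
            templates = find_templates(int(h), cohort, consensus, rule)
            p = impute_haplotype(templates, cohort)
            cache[key] = p
        hap_probs[study_order[int(h)]] = p

    n_ind = cohort.study_pairs.shape[0]
    probs = np.empty((n_ind, n_masked, 3))
    best = np.empty((n_ind, n_masked), dtype=np.int8)
    for i, (a, b) in enumerate(cohort.study_pairs):
        pr, bg = impute_individual(
            hap_probs[study_order[int(a)]], hap_probs[study_order[int(b)]], ref_freq
        )
        probs[i] = pr
        best[i] = bg
    return GenotypePosterior(
        pairs=cohort.study_pairs.copy(),
        masked_idx=cohort.masked_idx.copy(),
        probs=probs,
        best_guess=best,
        hap_ids=cohort.study_ids.copy(),
        hap_allele_probs=hap_probs,
    )
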