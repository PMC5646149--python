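"""Haplotype cohort simulation under the Kingman coalescent.

Generates gene genealogies for a panmictic constant-size population and two
demographic extensions -- exponential growth starting at a fixed epoch
before present, and a clean split of the population into ``beta``
subpopulations with no post-split migration -- then overlays a fixed number
of infinite-sites mutations, splits the sample into study and reference
haplotypes, pairs haplotypes into diploid individuals and selects the
subset of sites treated as directly measured.

Times handed to users are expressed in generations (or years via the
generation time); internally everything runs in coalescent units of
``2 * N_e`` generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._tree import GeneTree

__all__ = [
    "DemographyModel",
    "SimConfig",
    "HaplotypeMatrix",
    "Cohort",
    "sample_genealogy",
    "overlay_mutations",
    "make_cohort",
    "choose_measured_sites",
    "simulate_cohort",
]


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class DemographyModel:
    """Demographic scenario for genealogy simulation.

    Parameters
    ----------
    n_e
        Diploid effective population size at sampling time.
    growth_rate_alpha
        Exponential growth rate per generation (e.g. ``0.05`` for 5%).
        ``0`` means constant size.
    growth_onset_generations
        Generations before present at which growth started.  Looking
        backward, the population shrinks exponentially until this epoch and
        stays at the (small) ancestral size ``N_e * exp(-alpha * onset)``
        beyond it.
    n_subpops_beta
        Number of subpopulations.  ``1`` means panmixia; for ``beta > 1``
        the population consists of ``beta`` equal-sized demes (summing to
        ``n_e``) that merge, looking backward, into a single panmictic
        ancestral population at the split time.
    split_time_generations
        Generations before present of the clean split.
    subpop_hap_counts
        Haplotypes sampled per subpopulation (defaults to an equal split).
    generation_time_years
        Years per generation, used to convert year-based epochs.
    """

    n_e: float = 10_000.0
    growth_rate_alpha: float = 0.0
    growth_onset_generations: float = 200.0
    n_subpops_beta: int = 1
    split_time_generations: float = 2000.0
    subpop_hap_counts: tuple[int, ...] | None = None
    generation_time_years: float = 25.0

    # -- unit conversions ------------------------------------------------
    @property
    def alpha_internal(self) -> float:
        """Growth rate per coalescent unit (2*N_e generations)."""
        return self.growth_rate_alpha * 2.0 * self.n_e

    @property
    def onset_internal(self) -> float:
        return self.growth_onset_generations / (2.0 * self.n_e)

    @property
    def split_internal(self) -> float:
        return self.split_time_generations / (2.0 * self.n_e)

    def generations_to_internal(self, generations: float) -> float:
        return generations / (2.0 * self.n_e)

    def years_to_internal(self, years: float) -> float:
        return self.generations_to_internal(years / self.generation_time_years)

    # -- validation ------------------------------------------------------
    def validate(self, n_haplotypes: int | None = None) -> None:
        if self.n_e <= 0:
            raise ValueError("n_e must be positive")
        if self.growth_rate_alpha < 0:
            raise ValueError("growth_rate_alpha must be >= 0")
        if self.n_subpops_beta < 1:
            raise ValueError("n_subpops_beta must be >= 1")
        if self.n_subpops_beta > 1:
            if self.split_time_generations <= 0:
                raise ValueError("split_time_generations must be > 0 when beta > 1")
            if self.growth_rate_alpha > 0 and not (
                self.growth_onset_generations < self.split_time_generations
            ):
                raise ValueError("growth onset must predate the split (onset < split time)")
            if self.subpop_hap_counts is not None:
                if len(self.subpop_hap_counts) != self.n_subpops_beta:
                    raise ValueError("subpop_hap_counts length must equal n_subpops_beta")
                if n_haplotypes is not None and sum(self.subpop_hap_counts) != n_haplotypes:
                    raise ValueError("subpop_hap_counts must sum to the total sample size")

    def hap_counts(self, n: int) -> list[int]:
        """Haplotypes sampled per deme (equal split by default)."""
        beta = self.n_subpops_beta
        if beta == 1:
            return [n]
        if self.subpop_hap_counts is not None:
            if sum(self.subpop_hap_counts) != n:
                raise ValueError("subpop_hap_counts must sum to the sample size")
            return list(self.subpop_hap_counts)
        if n % beta != 0:
            raise ValueError(
                f"sample size {n} is not divisible by beta={beta}; "
                "set subpop_hap_counts explicitly"
            )
        return [n // beta] * beta

    # -- population size trajectory --------------------------------------
    # nu(t) = N(t)/N_e, with t in coalescent units looking backward:
    # nu(t) = exp(-a * min(t, t_onset)), a = alpha_internal.
    def relative_size(self, t):
        a, t0 = self.alpha_internal, self.onset_internal
        if a == 0:
            return np.ones_like(np.asarray(t, dtype=float))
        return np.exp(-a * np.minimum(np.asarray(t, dtype=float), t0))

    def coalescent_intensity(self, t):
        """Integral of 1/nu(s) ds from 0 to t (per-pair coalescent intensity)."""
        a, t0 = self.alpha_internal, self.onset_internal
        t = np.asarray(t, dtype=float)
        if a == 0:
            return t
        below = np.minimum(t, t0)
        lam = np.expm1(a * below) / a
        return lam + np.where(t > t0, (t - t0) * np.exp(a * t0), 0.0)

    def intensity_inverse(self, y: float) -> float:
        a, t0 = self.alpha_internal, self.onset_internal
        if a == 0:
            return y
        y0 = np.expm1(a * t0) / a
        if y <= y0:
            return np.log1p(a * y) / a
        return t0 + (y - y0) * np.exp(-a * t0)


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of a simulated cohort.

    Defaults mirror the baseline scenario: 1000 haplotypes with 100
    polymorphic sites over a ~20 kb segment (mu = 1.25e-8 per site per
    generation), 80% of haplotypes assigned to the study population and
    10% of sites directly measured.
    """

    n_haplotypes: int = 1000
    n_sites_S: int = 100
    seq_length_bp_L: int = 20_000
    mu_per_site: float = 1.25e-8
    study_fraction: float = 0.8
    measured_fraction: float = 0.1
    seed_sim: int = 0
    seed_sites: int = 0

    def validate(self) -> None:
        if self.n_haplotypes < 2:
            raise ValueError("n_haplotypes must be >= 2")
        if not 0 < self.study_fraction < 1:
            raise ValueError("study_fraction must lie in (0, 1)")
        if not 0 < self.measured_fraction <= 1:
            raise ValueError("measured_fraction must lie in (0, 1]")
        if self.n_sites_S < 1:
            raise ValueError("n_sites_S must be >= 1")
        if self.n_sites_S > self.seq_length_bp_L:
            raise ValueError("cannot place more sites than base pairs")


# ----------------------------------------------------------------------
@dataclass
class HaplotypeMatrix:
    """Binary haplotype-by-site matrix (0 ancestral / 1 derived)."""

    ids: list[str]
    positions: np.ndarray  # 1-based bp positions, strictly increasing
    alleles: np.ndarray  # (n_hap, n_sites) uint8

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotypes x sites)")
        if self.alleles.shape != (len(self.ids), self.positions.size):
            raise ValueError("inconsistent ids/positions/alleles shapes")
        if self.positions.size > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def derived_freq(self) -> np.ndarray:
        return self.alleles.mean(axis=0)

    def minor_allele_freq(self) -> np.ndarray:
        f = self.derived_freq()
        return np.minimum(f, 1.0 - f)

    def is_polymorphic(self) -> np.ndarray:
        s = self.alleles.sum(axis=0)
        return (s > 0) & (s < self.n_haplotypes)


# ----------------------------------------------------------------------
@dataclass
class Cohort:
    """Study/reference split of a simulated haplotype sample.

    Haplotype and site indices refer to rows/columns of ``haps``, which
    doubles as the held-out truth.
    """

    haps: HaplotypeMatrix
    study_ids: np.ndarray
    reference_ids: np.ndarray
    study_pairs: np.ndarray  # (n_study_individuals, 2)
    reference_pairs: np.ndarray
    measured_idx: np.ndarray
    masked_idx: np.ndarray
    demes: np.ndarray | None = None  # per-haplotype subpopulation

    def __post_init__(self):
        n = self.haps.n_haplotypes
        all_ids = np.sort(np.concatenate([self.study_ids, self.reference_ids]))
        if not np.array_equal(all_ids, np.arange(n)):
            raise ValueError("study and reference ids must partition all haplotypes")
        paired = np.sort(np.concatenate([self.study_pairs.ravel(), self.reference_pairs.ravel()]))
        if not np.array_equal(paired, np.arange(n)):
            raise ValueError("diploid pairing must cover every haplotype exactly once")
        sites = np.sort(np.concatenate([self.measured_idx, self.masked_idx]))
        if not np.array_equal(sites, np.arange(self.haps.n_sites)):
            raise ValueError("measured and masked indices must partition all sites")

    @property
    def n_study_individuals(self) -> int:
        return self.study_pairs.shape[0]

    def with_measured(self, measured_idx: np.ndarray) -> "Cohort":
        """Same cohort with a different measured-site selection."""
        measured_idx = np.sort(np.asarray(measured_idx, dtype=np.int64))
        masked = np.setdiff1d(np.arange(self.haps.n_sites), measured_idx)
        return replace(self, measured_idx=measured_idx, masked_idx=masked)

    def measured_haplotypes(self) -> np.ndarray:
        """Allele matrix of all haplotypes restricted to measured sites."""
        return self.haps.alleles[:, self.measured_idx]

    def genotypes(self, pairs: np.ndarray, site_idx: np.ndarray) -> np.ndarray:
        """Diploid genotypes (derived-allele dosage) for given pairs/sites."""
        a = self.haps.alleles[:, site_idx].astype(np.int8)
        return a[pairs[:, 0]] + a[pairs[:, 1]]

    def study_truth(self) -> np.ndarray:
        """True genotypes of study individuals at masked sites."""
        return self.genotypes(self.study_pairs, self.masked_idx)


# ----------------------------------------------------------------------
def _coalesce_phase(active, t_start, t_end, size_fraction, dem, rng, parent, time, next_id):
    """Run pairwise coalescence among ``active`` lineages from ``t_start``
    until ``t_end`` (or until one lineage remains).

    ``size_fraction`` scales the deme size: the per-pair rate at time t is
    ``1 / (size_fraction * nu(t))``.  Returns the updated lineage list and
    next free node id.
    """
    t = t_start
    while len(active) >= 2:
        k = len(active)
        pair_rate = 0.5 * k * (k - 1) / size_fraction
        target = dem.coalescent_intensity(t) + rng.exponential() / pair_rate
        t_new = dem.intensity_inverse(target)
        if t_new >= t_end:
            break
        i = rng.integers(k)
        j = rng.integers(k - 1)
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        node = next_id
        parent[a] = node
        parent[b] = node
        time[node] = t_new
        # remove the two merged lineages, append the new one
        for idx in sorted((i, j), reverse=True):
            active.pop(idx)
        active.append(node)
        next_id += 1
        t = t_new
    return active, next_id


def sample_genealogy(
    n: int,
    demography: DemographyModel | None = None,
    rng: np.random.Generator | None = None,
) -> GeneTree:
    """Draw a random genealogy of ``n`` haplotypes.

    Under panmixia this is the standard Kingman coalescent with
    time-rescaling for exponential growth.  With ``beta > 1`` demes,
    lineages coalesce only within their deme before the split time
    (each deme holding a fraction ``1/beta`` of the total size); at the
    split all remaining lineages merge into one panmictic ancestral
    population.
    """
    if n < 2:
        raise ValueError("need at least two haplotypes to build a genealogy")
    dem = demography if demography is not None else DemographyModel()
    dem.validate(n)
    rng = np.random.default_rng() if rng is None else rng

    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int32)
    time = np.zeros(n_nodes)
    next_id = n

    beta = dem.n_subpops_beta
    if beta == 1:
        active = list(range(n))
        active, next_id = _coalesce_phase(
            active, 0.0, np.inf, 1.0, dem, rng, parent, time, next_id
        )
        demes = None
    else:
        counts = dem.hap_counts(n)
        demes = np.repeat(np.arange(beta, dtype=np.int32), counts)
        t_split = dem.split_internal
        survivors: list[int] = []
        offset = 0
        for d in range(beta):
            deme_active = list(range(offset, offset + counts[d]))
            offset += counts[d]
            deme_active, next_id = _coalesce_phase(
                deme_active, 0.0, t_split, 1.0 / beta, dem, rng, parent, time, next_id
            )
            survivors.extend(deme_active)
        survivors, next_id = _coalesce_phase(
            survivors, t_split, np.inf, 1.0, dem, rng, parent, time, next_id
        )
    tree = GeneTree(parent, time, n, demes=demes)
    return tree


# ----------------------------------------------------------------------
def overlay_mutations(
    tree: GeneTree,
    n_sites_S: int,
    seq_length_bp: int,
    rng: np.random.Generator | None = None,
) -> HaplotypeMatrix:
    """Place exactly ``n_sites_S`` infinite-sites mutations on a genealogy.

    Each site's mutation falls on one branch chosen with probability
    proportional to branch length; carriers of the derived allele are the
    leaves below that branch.  Positions are drawn uniformly without
    replacement from ``1..seq_length_bp`` and sorted.
    """
    if tree.n_leaves < 2:
        raise ValueError("tree must have at least two leaves")
    if n_sites_S < 1:
        raise ValueError("n_sites_S must be >= 1")
    if n_sites_S > seq_length_bp:
        raise ValueError("cannot place more polymorphic sites than base pairs")
    rng = np.random.default_rng() if rng is None else rng

    b = tree.branch_lengths()
    probs = b / b.sum()
    branches = rng.choice(tree.n_nodes, size=n_sites_S, p=probs)
    positions = np.sort(rng.choice(seq_length_bp, size=n_sites_S, replace=False)) + 1

    packed = tree.leaf_masks_packed()
    n = tree.n_leaves
    alleles = np.zeros((n, n_sites_S), dtype=np.uint8)
    for j, node in enumerate(branches):
        carriers = np.unpackbits(packed[node])[:n]
        alleles[:, j] = carriers
    return HaplotypeMatrix(ids=list(tree.labels), positions=positions, alleles=alleles)


# ----------------------------------------------------------------------
def _random_pairs(ids: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if ids.size % 2 != 0:
        raise ValueError(
            f"cannot pair an odd number of haplotypes ({ids.size}) into diploids"
        )
    perm = rng.permutation(ids)
    return perm.reshape(-1, 2)


def make_cohort(
    haps: HaplotypeMatrix,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    measured_idx: np.ndarray | None = None,
    demes: np.ndarray | None = None,
) -> Cohort:
    """Randomly split haplotypes into study/reference sets and pair them
    into diploid individuals.

    The study set holds ``round(study_fraction * n)`` haplotypes; both the
    study and the reference partition must have even size so that random
    diploid pairing is possible.  If ``measured_idx`` is omitted, measured
    sites are drawn with :func:`choose_measured_sites`.
    """
    rng = np.random.default_rng() if rng is None else rng
    n = haps.n_haplotypes
    n_study = round(config.study_fraction * n)
    n_ref = n - n_study
    if n_study % 2 != 0 or n_ref % 2 != 0:
        raise ValueError(
            f"study/reference sizes must be even for diploid pairing, got "
            f"{n_study} study + {n_ref} reference haplotypes"
        )
    perm = rng.permutation(n)
    study_ids = np.sort(perm[:n_study])
    ref_ids = np.sort(perm[n_study:])
    study_pairs = _random_pairs(study_ids, rng)
    ref_pairs = _random_pairs(ref_ids, rng)
    if measured_idx is None:
        measured_idx = choose_measured_sites(haps, config.measured_fraction, rng=rng)
    measured_idx = np.sort(np.asarray(measured_idx, dtype=np.int64))
    masked_idx = np.setdiff1d(np.arange(haps.n_sites), measured_idx)
    return Cohort(
        haps=haps,
        study_ids=study_ids,
        reference_ids=ref_ids,
        study_pairs=study_pairs,
        reference_pairs=ref_pairs,
        measured_idx=measured_idx,
        masked_idx=masked_idx,
        demes=demes,
    )


def choose_measured_sites(
    haps: HaplotypeMatrix,
    measured_fraction: float,
    compatible_only: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Select the site indices treated as directly measured.

    ``round(measured_fraction * n_sites)`` indices are sampled uniformly
    without replacement.  With ``compatible_only`` the eligible pool is
    first reduced to a maximal pairwise four-gamete-compatible subset by
    greedy left-to-right retention (data from a single tree passes the
    screen unchanged).
    """
    rng = np.random.default_rng() if rng is None else rng
    n_sites = haps.n_sites
    n_measured = round(measured_fraction * n_sites)
    if compatible_only:
        from .genealogy import four_gamete_compatible

        kept: list[int] = []
        for j in range(n_sites):
            col = haps.alleles[:, j]
            if all(four_gamete_compatible(haps.alleles[:, k], col) for k in kept):
                kept.append(j)
        eligible = np.array(kept, dtype=np.int64)
    else:
        eligible = np.arange(n_sites, dtype=np.int64)
    if eligible.size < n_measured:
        raise ValueError(
            f"only {eligible.size} eligible sites but {n_measured} measured sites requested"
        )
    return np.sort(rng.choice(eligible, size=n_measured, replace=False))


# ----------------------------------------------------------------------
def simulate_cohort(
    config: SimConfig | None = None,
    demography: DemographyModel | None = None,
) -> Cohort:
    """Full simulation pipeline: genealogy, mutations, cohort assembly.

    ``config.seed_sim`` drives the genealogy, mutation overlay and the
    study/reference split; ``config.seed_sites`` drives the measured-site
    selection, so site selections can be re-drawn on a fixed cohort.
    """
    config = SimConfig() if config is None else config
    config.validate()
    dem = DemographyModel() if demography is None else demography
    dem.validate(config.n_haplotypes)

    rng_sim = np.random.default_rng(config.seed_sim)
    tree = sample_genealogy(config.n_haplotypes, dem, rng_sim)
    haps = overlay_mutations(tree, config.n_sites_S, config.seq_length_bp_L, rng_sim)
    rng_sites = np.random.default_rng(config.seed_sites)
    measured = choose_measured_sites(haps, config.measured_fraction, rng=rng_sites)
    return make_cohort(haps, config, rng_sim, measured_idx=measured, demes=tree.demes)
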