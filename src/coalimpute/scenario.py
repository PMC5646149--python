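"""Scenario orchestration: simulate -> infer -> consensus -> impute ->
evaluate over replicate and site-selection loops.

A scenario is a simulation design (sample size, demography), an inference
configuration (priors, demography mode, MCMC settings) and replicate
counts: ``n_sim_replicates`` independent haplotype simulations, each
re-used for ``n_site_selections`` independent draws of the measured
sites.  Both imputation methods run on identical cohorts and results are
aggregated into one row per (method, MAF stratum) with mean concordance,
normal-approximation 95% CI and mean IQS.

Reproducibility: every stochastic stage consumes a child seed derived
from the scenario seed through ``numpy.random.SeedSequence`` spawning --
``spawn_key = (replicate,)`` for haplotype simulation, cohort assembly
and inference, ``spawn_key = (replicate, selection)`` for measured-site
selection -- so any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import genealogy, hmm, impute, metrics
from .consensus import annotate_clade_times, majority_consensus
from .simulate import (
    Cohort,
    DemographyModel,
    SimConfig,
    choose_measured_sites,
    make_cohort,
    overlay_mutations,
    sample_genealogy,
)

__all__ = ["ScenarioConfig", "run_scenario", "stage_seed"]


def stage_seed(scenario_seed: int, *spawn_key: int) -> int:
    """Deterministic child seed (< 2^31) for a named pipeline stage."""
    ss = np.random.SeedSequence(entropy=scenario_seed, spawn_key=tuple(spawn_key))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class ScenarioConfig:
    """Complete description of one simulation scenario.

    Defaults mirror the baseline design: 10 simulation replicates each
    combined with 10 independent measured-site selections, 1000 MCMC
    genealogies per configuration, both imputation methods enabled.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    demography: DemographyModel = field(default_factory=DemographyModel)
    priors: genealogy.PriorConfig = field(default_factory=genealogy.PriorConfig)
    rule: impute.TemplateRule = field(default_factory=impute.TemplateRule)
    mode: str = "basic"
    n_sim_replicates: int = 10
    n_site_selections: int = 10
    n_trees: int = 1000
    burn_in: int | None = None
    thinning: int = 3
    run_coalescent: bool = True
    run_hmm: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_sim_replicates < 1 or self.n_site_selections < 1:
            raise ValueError("replicate counts must be >= 1")

    # -- serialisation ---------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "n_haplotypes": self.sim.n_haplotypes,
            "n_sites": self.sim.n_sites_S,
            "seq_length_bp": self.sim.seq_length_bp_L,
            "mu": self.sim.mu_per_site,
            "study_fraction": self.sim.study_fraction,
            "measured_fraction": self.sim.measured_fraction,
            "n_e": self.demography.n_e,
            "alpha": self.demography.growth_rate_alpha,
            "growth_onset_years": self.demography.growth_onset_generations
            * self.demography.generation_time_years,
            "beta": self.demography.n_subpops_beta,
            "split_time_years": self.demography.split_time_generations
            * self.demography.generation_time_years,
            "generation_time_years": self.demography.generation_time_years,
            "delta_generations": self.rule.delta_generations,
            "mode": self.mode,
            "n_sim_replicates": self.n_sim_replicates,
            "n_site_selections": self.n_site_selections,
            "n_trees": self.n_trees,
            "thinning": self.thinning,
            "run_coalescent": self.run_coalescent,
            "run_hmm": self.run_hmm,
            "seed": self.seed,
            "theta_prior": [self.priors.theta_lo, self.priors.theta_hi],
        }
        if self.burn_in is not None:
            doc["burn_in"] = self.burn_in
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        gen_time = float(doc.get("generation_time_years", 25.0))
        sim = SimConfig(
            n_haplotypes=int(doc.get("n_haplotypes", 1000)),
            n_sites_S=int(doc.get("n_sites", 100)),
            seq_length_bp_L=int(doc.get("seq_length_bp", 20_000)),
            mu_per_site=float(doc.get("mu", 1.25e-8)),
            study_fraction=float(doc.get("study_fraction", 0.8)),
            measured_fraction=float(doc.get("measured_fraction", 0.1)),
        )
        dem = DemographyModel(
            n_e=float(doc.get("n_e", 10_000)),
            growth_rate_alpha=float(doc.get("alpha", 0.0)),
            growth_onset_generations=float(doc.get("growth_onset_years", 5000.0)) / gen_time,
            n_subpops_beta=int(doc.get("beta", 1)),
            split_time_generations=float(doc.get("split_time_years", 50_000.0)) / gen_time,
            generation_time_years=gen_time,
        )
        theta_prior = doc.get("theta_prior", [0.0, 100.0])
        priors = genealogy.PriorConfig(
            theta_lo=float(theta_prior[0]), theta_hi=float(theta_prior[1])
        )
        rule = impute.TemplateRule(
            delta_generations=float(doc.get("delta_generations", 10.0)),
            n_e=dem.n_e,
        )
        return cls(
            sim=sim,
            demography=dem,
            priors=priors,
            rule=rule,
            mode=str(doc.get("mode", "basic")),
            n_sim_replicates=int(doc.get("n_sim_replicates", 10)),
            n_site_selections=int(doc.get("n_site_selections", 10)),
            n_trees=int(doc.get("n_trees", 1000)),
            burn_in=doc.get("burn_in"),
            thinning=int(doc.get("thinning", 3)),
            run_coalescent=bool(doc.get("run_coalescent", True)),
            run_hmm=bool(doc.get("run_hmm", True)),
            seed=int(doc.get("seed", 0)),
        )


# ----------------------------------------------------------------------
def _run_coalescent_method(cohort: Cohort, config: ScenarioConfig, rng):
    measured = cohort.haps.alleles[:, cohort.measured_idx]
    sample = genealogy.mcmc_sample(
        measured,
        priors=config.priors,
        demography=config.demography,
        mode=config.mode,
        n_samples=config.n_trees,
        burn_in=config.burn_in,
        thinning=config.thinning,
        rng=rng,
        leaf_demes=cohort.demes if config.mode in ("structure", "growth-structure") else None,
    )
    consensus = annotate_clade_times(majority_consensus(sample), sample)
    return impute.impute_cohort(cohort, consensus, config.rule)


def run_scenario(config: ScenarioConfig, progress=None) -> pd.DataFrame:
    """Execute the full replicate loop of a scenario.

    Returns one row per (method, MAF stratum) with the replicate mean,
    95% CI and mean IQS -- the machine-readable analogue of the accuracy
    tables.  ``progress`` may be a callable receiving
    ``(replicate, selection)`` after each inner iteration.
    """
    records: list[dict] = []
    for r in range(config.n_sim_replicates):
        rng_sim = np.random.default_rng(stage_seed(config.seed, r))
        tree = sample_genealogy(config.sim.n_haplotypes, config.demography, rng_sim)
        haps = overlay_mutations(
            tree, config.sim.n_sites_S, config.sim.seq_length_bp_L, rng_sim
        )
        base_cohort = make_cohort(
            haps, config.sim, rng_sim,
            measured_idx=np.arange(round(config.sim.measured_fraction * haps.n_sites)),
            demes=tree.demes,
        )
        for s in range(config.n_site_selections):
            try:
                rng_sites = np.random.default_rng(stage_seed(config.seed, r, s))
                measured = choose_measured_sites(
                    haps, config.sim.measured_fraction, rng=rng_sites
                )
                cohort = base_cohort.with_measured(measured)
                if config.run_coalescent:
                    rng_mcmc = np.random.default_rng(stage_seed(config.seed, r, s, 1))
                    post = _run_coalescent_method(cohort, config, rng_mcmc)
                    table = metrics.evaluate_imputation(cohort, post)
                    for row in table.itertuples():
                        records.append({
                            "replicate": r, "selection": s, "method": "coalescent",
                            "maf_category": row.maf_category,
                            "n_variants": row.n_variants,
                            "concordance": row.concordance, "iqs": row.iqs,
                        })
                if config.run_hmm:
                    post = hmm.impute_cohort_hmm(cohort)
                    table = metrics.evaluate_imputation(cohort, post)
                    for row in table.itertuples():
                        records.append({
                            "replicate": r, "selection": s, "method": "hmm",
                            "maf_category": row.maf_category,
                            "n_variants": row.n_variants,
                            "concordance": row.concordance, "iqs": row.iqs,
                        })
            except Exception as exc:
                raise RuntimeError(
                    f"scenario failed at simulation replicate {r}, site selection {s}"
                ) from exc
            if progress is not None:
                progress(r, s)
    per_rep = pd.DataFrame.from_records(records)
    rows = []
    for (method, cat), grp in per_rep.groupby(["method", "maf_category"], sort=False):
        mean, (lo, hi) = metrics.summarize_replicates(grp["concordance"].to_numpy())
        iqs_mean, _ = metrics.summarize_replicates(grp["iqs"].to_numpy())
        rows.append({
            "method": method,
            "maf_category": cat,
            "n_variants": float(grp["n_variants"].mean()),
            "mean_concordance": mean,
            "ci_lo": lo,
            "ci_hi": hi,
            "mean_iqs": iqs_mean,
            "n_replicates": len(grp),
        })
    summary = pd.DataFrame(rows)
    summary.attrs["per_replicate"] = per_rep
    return summary
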