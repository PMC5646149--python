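# coalimpute

Coalescent-based genotype imputation within LD-blocks, with a ρ = 0
haplotype-copying HMM as the standard-imputation comparator.

## The problem

Genotype imputation fills in variants that were not directly typed in a
study by borrowing information from a fully sequenced reference panel.
Standard methods exploit present-day linkage disequilibrium (LD). Inside
an *LD-block* — a segment with negligible historical recombination — every
variant descends from a single gene genealogy, so an alternative is to
estimate that genealogy explicitly and copy masked alleles from the
reference haplotypes that share the most recent common ancestry with each
study haplotype. `coalimpute` implements this coalescent-based approach
end to end, for population-genetics researchers who want a reproducible,
scriptable re-implementation of the whole pipeline: simulation, Bayesian
genealogy inference, consensus-tree construction, template-based
imputation, the HMM comparator, and accuracy scoring.

## The method

1. **Simulation** (`coalimpute.simulate`). Haplotype cohorts are drawn
   from the Kingman coalescent (N_e = 10,000 by default) without
   recombination, optionally with exponential growth (rate α per
   generation from a fixed onset) or a clean split into β equal
   subpopulations; exactly S infinite-sites mutations are overlaid
   (S = 100 over 20 kb by default, µ = 1.25 × 10⁻⁸). Haplotypes are split
   into study (80%) and reference (20%) sets, paired into diploids, and
   10% of sites are marked as directly measured; the remaining study
   genotypes are masked.
2. **Genealogy inference** (`coalimpute.genealogy`). From the
   measured-site matrix of all haplotypes, an MCMC sampler draws posterior
   genealogies. Under infinite sites the data fix a perfect-phylogeny
   skeleton, and the chain explores its time-resolved binary refinements
   together with the scaled mutation rate θ ~ uniform(0, 100) (plus α or
   subpopulation proportions in the demographic modes). The likelihood is
   the explicit infinite-sites form
   `Σ_s log(b_s/T) + log Poisson(S; θT/2)`.
3. **Consensus** (`coalimpute.consensus`). The tree sample collapses into
   a majority-rule consensus whose clades carry support values and mean
   posterior coalescence times.
4. **Imputation** (`coalimpute.impute`). Reference haplotypes identical to
   a study haplotype at the measured sites are its templates; failing
   that, every reference haplotype whose TMRCA on the consensus tree lies
   within 10 generations of the minimum. Masked-allele probabilities are
   template allele frequencies; haplotype pairs combine independently into
   genotype probabilities P(G = 0/1/2).
5. **Comparator** (`coalimpute.hmm`). A diploid Li–Stephens
   genotype-copying HMM, `P(G|H, µ, ρ) = Σ_Z P(G|Z, µ) P(Z|H, ρ)`,
   evaluated exactly at ρ = 0 (constant copying pair; weighted enumeration
   of all N² ordered reference pairs).
6. **Metrics** (`coalimpute.metrics`). Genotype concordance, the
   chance-corrected imputation quality score (IQS, a per-variant Cohen's
   kappa), MAF stratification (rare ≤ 0.01 < low-frequency ≤ 0.05 <
   common), normal-approximation 95% CIs across replicates, and t/F method
   comparisons.

See `docs/methods.md` for model details, priors, MCMC moves, numerical
choices and limitations.

## Worked example

```python
import numpy as np
import coalimpute as ci
from coalimpute.metrics import evaluate_imputation

# a small cohort: 200 haplotypes, 100 sites, 10 measured
cohort = ci.simulate_cohort(ci.SimConfig(n_haplotypes=200, seed_sim=1, seed_sites=1001))

# posterior genealogies from the measured sites, consensus, imputation
sample = ci.mcmc_sample(cohort.haps.alleles[:, cohort.measured_idx],
                        n_samples=200, thinning=3, rng=np.random.default_rng(7))
cons = ci.annotate_clade_times(ci.majority_consensus(sample), sample)
post = ci.impute_cohort(cohort, cons)
print(evaluate_imputation(cohort, post))

# the rho = 0 copying-HMM comparator on the identical cohort
print(evaluate_imputation(cohort, ci.impute_cohort_hmm(cohort)))
```

Output (coalescent method first, then the HMM):

```
    maf_category  n_variants  concordance       iqs
0            all          90     0.951806  0.449519
1           rare          24     0.989583  0.000000
2  low-frequency          29     0.918534  0.199755
3         common          37     0.953378  0.820768
    maf_category  n_variants  concordance       iqs
0            all          90     0.951806  0.449519
1           rare          24     0.989583  0.000000
2  low-frequency          29     0.918534  0.199755
3         common          37     0.953378  0.820768
```

`n_variants` counts the masked, non-monomorphic variants per MAF stratum;
`concordance` is the fraction of correctly best-guessed genotypes over
all 80 study individuals, and `iqs` the mean per-variant chance-corrected
agreement (high rare-variant concordance earns a *low* IQS because
calling everyone homozygous-ancestral is already right by chance). On
this particular cohort the two methods make identical calls — in a
recombination-free block the ten measured genotypes usually pin down the
same donors for both; across replicates the methods do differ, mostly at
common variants.

The same pipeline is available from the shell:

```bash
coalimpute simulate --out-dir cohort --seed 1
coalimpute infer-trees --cohort cohort --n-trees 200 --seed 7 --out trees.nwk
coalimpute consensus --trees trees.nwk --out consensus.nwk
coalimpute impute --consensus trees.nwk --cohort cohort --out imputed.gen
coalimpute baseline --cohort cohort --out baseline.gen
coalimpute evaluate --cohort cohort --gen imputed.gen
coalimpute run-scenario --out-dir results --seed 1   # full replicate loop
```

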