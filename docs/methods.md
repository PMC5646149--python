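# Methods

`coalimpute` imputes missing genotypes inside an LD-block — a chromosomal
segment with negligible historical recombination, so that every variant in
the segment descends from a single gene genealogy. Instead of modelling
present-day LD directly, the method estimates the posterior distribution of
that genealogy from the directly measured variants and copies masked
alleles from the reference haplotypes that coalesce first with each study
haplotype. A recombination-free Li–Stephens genotype-copying HMM provides
the standard-imputation comparator.

## Simulation model

Haplotype cohorts are generated under the Kingman coalescent without
recombination. Time is measured internally in units of `2·N_e` generations
(pair-coalescence rate 1 for a constant population); every user-facing
epoch or window is expressed in generations (or years via
`generation_time_years`, default 25) and converted internally.

Demographic extensions:

* **Exponential growth.** Forward in time the population grows at rate α
  per generation from a fixed onset epoch to the present, where it has size
  `N_e`; backward in time the size at `t` generations is `N_e·exp(−α·t)`
  until the onset and stays at the (small) ancestral size
  `N_e·exp(−α·t_onset)` beyond it. Coalescence times are drawn by analytic
  inversion of the piecewise-exponential coalescent intensity. At the study
  conditions (α between 1.25% and 5% per generation, onset 5000 years ago)
  the ancestral population is tiny, so genealogies become star-like with
  nearly all coalescences compressed around the onset epoch and the site
  frequency spectrum strongly singleton-shifted. This is the direct
  consequence of reading α per generation; the package makes the rate and
  onset fully configurable.
* **Clean-split structure.** `β ≥ 2` demes of equal size (summing to
  `N_e`) evolve independently backward in time — each deme's pair rate is
  scaled by its size fraction — until the split time, when all residual
  lineages merge into one panmictic ancestral population. There is no
  post-split migration.

Mutations follow the infinite-sites model conditioned on a fixed number of
segregating sites `S` (default 100 over a 20 kb segment): each site's
mutation lands on one branch with probability proportional to branch
length, and site positions are drawn uniformly without replacement. The
fixed-`S` design matches the study layout this package reproduces; the
per-site rate `μ` (default 1.25×10⁻⁸) enters only through the scaled
mutation rate used in inference.

A cohort assigns a fraction of haplotypes (default 0.8) to the study
population and the rest to the external reference panel, pairs haplotypes
at random into diploid individuals within each partition, and marks a
fraction of sites (default 0.1) as directly measured; all remaining study
genotypes are masked and later imputed. An optional pairwise four-gamete
screen restricts the measured-site pool to a greedily chosen compatible
subset, as needed for real data that contain recombinant variants;
single-tree simulated data always pass the screen unchanged.

### What the generator does and does not emulate

The generator reproduces the genealogical structure, allele-frequency
spectrum and study/reference sampling design of an idealised LD-block. It
does not emulate genotyping error, phasing error (study haplotypes are
known exactly), recombination within the block, gene conversion, recurrent
mutation, or ascertainment bias in which variants are typed. Passing tests
therefore demonstrate correctness of the algorithms under the ideal
no-recombination model, not robustness of the method on real data — the
latter depends mainly on how far a real segment deviates from a single
genealogy.

## Genealogy inference

Inference runs on the measured-site submatrix of **all** haplotypes (study
plus reference). Under infinite sites without recombination a compatible
binary matrix determines a unique perfect phylogeny whose internal nodes
are exactly the distinct derived-carrier sets of the columns; haplotypes
identical at the measured sites attach to a common node. The posterior over
genealogies is supported entirely on time-resolved binary refinements of
this skeleton, which shrinks the tree space enormously without discarding
posterior mass and is the defining implementation choice of the sampler.

The Metropolis-within-Gibbs chain state is: coalescence times of all
binary nodes, the binary resolution of each skeleton multifurcation, the
scaled mutation rate θ, and (when active) the growth rate α or the
subpopulation proportions. The target density is the coalescent prior on
times — constant-size, growth-rescaled via the same intensity function as
the simulator, or structured with within-deme rates before the split and
zero density for cross-deme coalescences earlier than the split — times an
explicit infinite-sites likelihood

    log L = Σ_sites log(b_s / T) + S·log(θT/2) − θT/2 − log S!,

where `b_s` is the length of the unique branch subtending site `s`'s
derived carriers and `T` the total tree length. Moves:

1. single-node time proposals, uniform within the interval bounded by the
   node's children and parent (the root uses a multiplicative slack
   proposal);
2. whole-tree rescaling of all internal times;
3. full re-resolution of one multifurcation — a fresh uniform labelled
   history with order-statistic times, which is proposal-symmetric;
4. a child-swap move that exchanges the attachment points of two children
   of one multifurcation (times unchanged). Full re-resolution alone
   cannot mix multifurcations with many children, because independently
   redrawing dozens of times is essentially never accepted; the swap move
   provides local topology mixing at any multifurcation size;
5. log-scale random walks on θ (uniform(0,100) prior), on α (gamma prior
   with shape 2 and rate chosen so the prior mean equals the scenario's
   growth rate), and pairwise mass transfers on the subpopulation
   proportions (symmetric Dirichlet prior with concentration 2). The split
   time is held fixed at its configured value (the simulation truth by
   default) since the data at ten measured sites carry almost no
   information about it.

Defaults: 1000 recorded trees, thinning 3 sweeps, burn-in 20% of the total
chain, proposal step sizes adapted towards ≈30% acceptance during burn-in
only (so the post-burn-in kernel is fixed and detailed balance holds). θ
is initialised at the Watterson estimate clipped into the prior support.

Correctness checks built into the test suite: with the likelihood switched
off the sampler's time marginals match direct coalescent simulation
(Kolmogorov–Smirnov), three-leaf topologies are uniform under the prior,
the likelihood agrees with brute-force mutation placement on small trees,
and 90% posterior intervals for θ cover the simulation truth at roughly
nominal rate.

## Consensus tree

The tree sample is collapsed into a majority-rule consensus: exactly the
clades appearing in strictly more than half of the sampled trees are
retained (strict majority avoids mutually incompatible 50/50 clades and
guarantees the retained set is pairwise nested or disjoint), and each
retained clade is annotated with the arithmetic mean, over the trees
containing it, of its MRCA time; the root clade's time is the mean root
time over all trees. Because means are taken over different subsets of
trees a child's mean can exceed its parent's; such children are clamped
down to the parent's time so TMRCA queries stay monotone along the tree.
Haplotypes identical at the measured sites generally end up attached to a
common multifurcation (their internal arrangement has no data support),
which is exactly the right representation for the template rule below.

## Template-based imputation

For each study haplotype:

1. if the reference panel contains haplotypes **identical at every
   measured site**, all of them are templates and the tree is not
   consulted;
2. otherwise the TMRCA (mean posterior time of the smallest retained clade
   containing both leaves) to every reference haplotype is examined, and
   every reference haplotype within `δ` of the minimum TMRCA serves as a
   template. The window `δ` defaults to 10 generations, converted
   internally via `2·N_e`; the window is anchored at the first-coalescing
   haplotype, so `δ = 0` selects the single nearest clade's references.

The masked-site allele probability is the derived-allele frequency among
the templates. The two haplotypes of an individual are combined as
independent: `P(G=2) = p_a·p_b`, `P(G=0) = (1−p_a)(1−p_b)`, `P(G=1)` the
remainder. Best-guess genotypes are the argmax, with exact ties broken
toward the genotype of larger Hardy–Weinberg probability at the
reference-panel allele frequency (a deterministic, frequency-consistent
rule), and any residual tie toward the smaller dosage. Study haplotypes
are never used as templates for other study haplotypes.

## The copying-HMM comparator

The comparator models each study individual's genotype vector as emitted
by an ordered pair of reference haplotypes, each copied allele flipping
independently with miscopy probability ε, and the copied pair switching
along the sequence at a rate set by the recombination map. With the map at
zero — the LD-block setting — the pair is constant and the posterior is an
exact weighted enumeration of the N² ordered pairs, vectorised across
individuals; a forward–backward implementation over the pair chain covers
nonzero maps and doubles as an independent code path that must agree with
the enumeration at rate zero. ε defaults to the Li–Stephens
population-genetic value `θ̃/(2(θ̃+N))` with `θ̃ = 1/Σ_{i<N} 1/i`. Measured
genotypes are taken as observed (the simulation provides them); masked
genotypes are marginalised out and re-estimated.

Because this comparator is the exact posterior of its model, its accuracy
is bounded below by marginal-frequency guessing; like any well-specified
Bayes rule it cannot be systematically worse than ignoring the data. Under
the no-recombination simulation design it turns out to be nearly as
accurate as the coalescent-tree method (the ten measured genotypes usually
pin down the copied pair), with its deficit concentrated at common
variants where the diploid sum leaves phase ambiguity.

## Metrics

Accuracy is the genotype concordance — the fraction of correctly
best-guessed genotypes over all study individuals and imputed variants —
plus the imputation quality score (IQS): per variant, Cohen's kappa of the
3×3 truth-vs-imputed table, which corrects for chance agreement implied by
the allele frequency; variant-level scores are averaged, skipping variants
whose chance agreement is exactly 1. Variants are stratified by minor
allele frequency: rare (MAF ≤ 0.01), low-frequency (0.01 < MAF ≤ 0.05),
common (MAF > 0.05); monomorphic variants are excluded. MAF is computed
from the true allele frequencies of the full simulated sample (study plus
reference) — the only definition available identically to both methods.
Replicate series are summarised as mean ± 1.96·sd/√n (normal
approximation), and methods are compared with a two-sample t-test on means
and an F-test on variances.

## Scenario runner and reproducibility

`run_scenario` executes the full loop — outer replicates re-simulate the
cohort, inner replicates re-draw the measured sites on the fixed cohort —
runs both methods on identical cohorts and aggregates one row per
(method, MAF stratum). Every stochastic stage consumes a child seed
derived from the scenario seed through `numpy.random.SeedSequence` with a
documented spawn key (`(replicate,)` for simulation, `(replicate,
selection)` for site selection, `(replicate, selection, 1)` for the MCMC),
so any stage can be re-run in isolation and whole runs are byte-identical
under a fixed seed.

## Problem sizes used in the shipped checks

The statistical checks in the test suite and the acceptance script run the
published study designs at reduced replicate counts (3–4 replicate pairs
instead of 10×10) and reduced MCMC sample sizes (100–250 recorded trees
instead of 1000), sizes at which the replicate means are stable to roughly
±0.01 concordance while a full run completes on one CPU in minutes. The
package itself has no such limits; the full design is a configuration
choice (`n_sim_replicates=10, n_site_selections=10, n_trees=1000`).

## Known limitations

* No recombination: a segment violating the single-genealogy assumption
  must be pre-filtered with the four-gamete screen, which discards real
  signal; ancestral recombination graphs are out of scope.
* The ancestral allele is assumed known (state 0), which is true for
  simulated data; real data would require polarisation.
* The structured prior conditions on known deme labels and a fixed split
  time; label inference and split-time estimation are not implemented.
* Consensus mean times mix estimates across tree subsets; the
  monotonicity clamp keeps queries consistent but slightly biases child
  clade times downward when support is marginal.
* With very few measured sites the perfect-phylogeny skeleton is coarse
  and most of the posterior concerns within-group resolutions that no data
  can inform; imputation accuracy then rests almost entirely on the
  identical-match rule.
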