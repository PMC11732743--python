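# Methods

This note documents the models, the numerical choices, what the
synthetic-data generators do and do not emulate, and the known limits of
agreement with the published reference values.  Nothing here states an
empirical number that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. The social-group model

A population is a fully connected network of `n_groups` social groups —
structure without space, as in an island model, except that the units are
not panmictic demes but small age-structured aggregations of kin.

**Individuals** carry sex, age (in ticks; one tick is a quarter of the
modeled species' year), a lifespan drawn at birth, a group id, a
reproductive-status (RS) flag, and a diploid genome of `n_loci`
microsatellites under the strict stepwise mutation model (SMM).

**Life history** (defaults; all in ticks): mean lifespan 28, hard cap 40,
weaning age 1, reproductive age 8, birth interval 4, infant mortality 0.3,
litter distribution truncated Poisson, per-allele mutation probability
μ = 5·10⁻⁴ per transmission.  The lifespan draw is Poisson(28) with draws
above 40 rejected (mean ≈ 27.85, computed by pmf enumeration in the
tests); an individual dies when its age exceeds its draw.

**One tick applies, in order:** aging (+1 to everyone), mortality,
reproduction, vacancy filling (migration/philopatric replacement),
colonization.  The order is fixed and documented because late-tick events
see the outcomes of earlier ones.

**Reproduction.** Each group holds `rs_males` + `rs_females` breeding
slots (1+1 monogamy, 2+2 polygynandry, 1+10 polygyny).  Every RS female at
or above reproductive age and at least `birth_interval` ticks past her
previous reproduction event is assigned exactly one RS male of her group,
uniformly (males may serve several females).  Her litter is drawn from
Poisson(mean = offspring_mean + 1 = 3) truncated one above its mean (≤ 4),
so E[litter] = 2.3817 (pmf enumeration).  Newborns die with probability
0.3 at birth (weaning is one tick away, so at-birth application is
equivalent), join the mother's group, have 1:1 random sex, and inherit one
uniformly chosen allele per locus from each parent; each transmitted
allele steps ±1 with probability μ.  The litter calibration is fixed by a
demographic balance argument: census per group =
rs_females · (1−infant_mortality) · E[litter]/birth_interval ·
E[lifetime] ≈ 10·0.417·28.8 ≈ 12 for monogamy, which reproduces the
reference equilibrium censuses (~600 monogamy, ~6000 polygyny at 50
groups) that the looser reading of the litter rule (Poisson(2) ≤ 3) misses
by a third.  No per-pair rule can simultaneously match the published
polygynandry census (~1000): with two breeding females per group the model
necessarily yields ≈ 2× the monogamy census (~1200, within 25% of the
published value but not 10%).

**Vacancies and dispersal.**  RS status, once gained, lasts until death.
A female vacancy is filled philopatrically: a uniform draw among the
group's own non-RS adult females, or nothing.  A male vacancy is filled by
a migrant male (uniform among non-RS adult males of *other* groups), but
only while the group still holds at least one RS female: males migrate to
breed, and a group without breeding females attracts no migrants.  A group
whose female line fails therefore dies out within a lifespan and is
re-founded by **colonization**: the first tick after a group is empty, a
full RS complement is drawn uniformly from all non-RS adults
population-wide (both sexes — colonization is the one event that overrides
philopatry), deferred while candidates of either sex are lacking.  The
male-migration condition is what keeps strictly philopatric populations
viable: if female-less groups kept absorbing migrant males they would
never empty, never be re-colonized, and monogamous populations would decay
to extinction (measured: 414 → 0 individuals in 6000 ticks under that
variant) instead of being stationary.

**Founding.**  Every group starts with its full RS complement of adults
aged exactly at reproductive age.  Founder alleles are drawn with
replacement, per locus, from a founding pool — a 200-gene-copy coalescent
SMM sample at θ = 20 (equilibrium diversity ≈ 0.84) — emulating foundation
by a few individuals from a large, diverse source population so that
mutation-drift equilibrium is approached from above (diversity decays to
its equilibrium instead of accumulating from zero).  Genetic equilibrium
at 50 groups is reached within ~20,000 ticks (He and F_ST flat
thereafter); scaled-down batteries run 50,000 ticks.

**What the generator does not emulate:** space and isolation by distance,
density regulation (census is a pure birth/death balance), extra-pair
paternity, dominance takeovers (RS is for life), variable group-size
ceilings, and selection (genotypes never feed back on demography — which
is also why census/RS studies legitimately run with genetics disabled).

## 2. Panmictic references

`wright_fisher.run_wf` is a non-overlapping-generations Wright–Fisher
simulator: 2000 haploids (θ = 2Nμ) or 1000 diploid dioecious individuals
(500♂/500♀, θ = 4Nμ), mutation ±1 with probability μ per transmitted
allele.  Default run length is 20N generations from a monomorphic start; a
fast mode initializes each locus from a coalescent sample of the whole
population at the matched θ — exactly stationary by construction — and
runs a 200-generation forward burn-in that only imposes the forward
process's pedigree fine structure.  The haploid model is clonal: all loci
of an individual descend from one parent, so loci share a single
genealogy.  That is the natural haploid life cycle, and it makes haploid
*datasets* (not loci) highly variable — the equilibrium test then
misfires in *both* directions across datasets, reproducing the published
two-sided anomaly of the haploid scenario.

`coalescent.simulate_genealogy` draws Kingman genealogies (rate k(k−1) in
4N-generation units, uniform pair choice); mutations are Poisson(θ ×
branch length) per branch with net ±1 displacements cascaded root-to-leaf
through the parent pointers (O(n), no incidence matrix).  Closed-form
oracles used throughout testing: E[total length] = Σ 1/i,
E[mutations] = θ·Σ 1/i, He_eq = 1 − 1/√(1+2θ).

## 3. The mutation-drift-equilibrium test

For each polymorphic locus (k ≥ 2 alleles among n genes) the observed
unbiased gene diversity He = n/(n−1)(1 − Σp²) is compared with the
distribution of Heq obtained from 1000 conditional coalescent replicates
at the same (n, k).  The conditional simulator adds SMM mutations one at a
time to a fresh genealogy (uniformly, probability ∝ branch length).
Because the SMM is homoplasic the allele count is non-monotone in the
mutation count, and the stopping rule matters:

* **first passage** — stop the instant the count first equals k.  The
  k-th allele is then typically young and rare, the retained
  configurations are maximally uneven, and the simulated Heq falls *below*
  the stationary He|k (measured at n = 40: 0.223 vs 0.337 for k = 2, 0.419
  vs 0.476 for k = 3).  A test built on this rule calls essentially every
  stationary θ = 2 dataset a bottleneck.
* **last exit** (the default) — keep mutating and retain the last
  k-allele configuration before the count first exceeds k.  Homoplasy has
  then reshuffled the configuration at that allele number; the simulated
  Heq sits slightly *above* stationary He|k (0.490 vs 0.476 at k = 3),
  which is the behavior of the reference implementation of this test: a
  mild systematic H-deficit ("expansion") bias on stationary data at
  moderate diversity.  Replicates that fail within a cap of 50·n mutations
  redraw the genealogy.

Both rules are exposed; the rejection-sampling oracle (stationary samples
across a θ grid, keeping exact-k configurations) lies strictly between
them, and the test suite pins that ordering.  Note the two desiderata are
mutually exclusive: a sampler that exactly matches stationary rejection
sampling is calibrated and cannot show the published 30% expansion rate.

Dataset-level significance: one-sided Wilcoxon signed-rank tests on the
per-locus standardized differences (He − mean Heq)/sd(Heq) (the reference
tool's "DH/sd"; standardization changes ranks, never signs), zeros
dropped, exact null enumeration up to 25 informative loci and the normal
approximation with continuity correction above, monomorphic and
degenerate (sd = 0) loci excluded.  Verdicts at α = 0.05: H-deficit →
expansion, H-excess → bottleneck, both → ambiguous, else equilibrium; no
multiplicity correction, mirroring field practice.  Within a dataset,
loci with equal (n, k) share one 1000-replicate Heq batch (they are draws
from the same distribution; the Monte-Carlo error of a batch mean is
~0.003 He units); `share_heq=False` restores strictly per-locus
simulation.

## 4. LD-based contemporary Ne

For every pair of retained alleles at every pair of loci, the Burrows
composite disequilibrium is estimated from unphased diploid genotypes as
Δ̂ = S/(S−1)·(mean(XY)/2 − 2 p_A p_B) (X, Y ∈ {0,1,2} are copy counts) and
standardized by the copy-count variances into the composite correlation
r² = Δ̂²/[(p_A q_A + D_A)(p_B q_B + D_B)], D being the within-locus
Hardy–Weinberg departure.  Alleles seen as a single copy are excluded
(they dominate r² noise); loci left with < 2 alleles are dropped; all
comparisons get unit weight, and with complete data the harmonic mean
sample size equals S.  The mean r² is decomposed as sampling +
drift:

    E[r²_sample] = 1/S + 3.19/S²                (S ≥ 30)
                 = 0.0018 + 0.907/S + 4.44/S²   (S < 30)
    N̂e = (a + sqrt(a² − b·r²_drift)) / (2·r²_drift)

with (a, b) = (1/3, 2.76) random mating S ≥ 30, (0.308, 2.08) S < 30,
(2/3, 7.2) lifetime monogamy S ≥ 30, (0.618, 5.24) S < 30 — the standard
empirical small-sample regressions of the LD method, kept in one table
(`ldne.BIAS_CORRECTIONS`); the discriminant is clamped at zero (it only
goes negative for single-digit Ne) and a non-positive drift signal yields
an infinite, flagged estimate, which the experiment layer removes only at
aggregation, as in the published workflow.  The monogamy inversion is
applied exactly when the data come from the monogamous scenario.

Validation: the estimator recovers known truths when the sample is a
proper subset of the population (medians 213 / 115 / 50.4 for true Ne of
200 / 100 / 50), with a modest upward edge bias when the entire population
is censused (S = N = 50 → median ≈ 60).  The recovery preset runs at
θ = 0.5 — the middle of the study's low-to-moderate diversity grid and
near the microsatellite mutation scale — because forcing θ = 2 onto
N = 50 requires a 1% per-locus mutation rate, and mutation at that rate
itself erodes inter-locus LD and biases N̂e upward.

## 5. Sampling and interchange

Samples are drawn from the final tick among offspring, juveniles, RS
individuals and non-RS females; non-RS adult males (dispersing floaters)
are never sampled.  Schemes: 20–100 individuals from a random pool of
groups (10-of-10, 30-of-50, 100-of-500), from a small pool of five groups,
or one individual per group (capped by the group count).  Pooling over the
small pool is free (not stratified).  GENEPOP export uses 3-digit codes
with a documented offset (default +100) recorded on the title line
together with the ploidy (haploids are written as homozygous diploids), so
round trips are lossless; codes outside 001–999 raise with the admissible
offset range.

## 6. Determinism, performance and scale choices

Every public function takes a `numpy.random.Generator`; experiment
replicates use recorded seeds `base_seed + r`, and rerunning any preset
reproduces its tables bit for bit.  The two hot loops — the social tick
and the conditional Heq simulation — have compiled (numba) kernels and
pure-numpy reference implementations with identical event rules; tests
compare the paths rule-by-rule and distributionally.  Kernels consume
randomness only through `Generator.random()`: discrete draws go through
inverse-CDF tables, gamete choices through 48-bit blocks extracted from
one double, and mutation placement through geometric skipping (memoryless,
so per-tick restarts are distribution-neutral).

Scaled-down batteries used by the tests: 20 replicates × 50,000 ticks ×
100 loci per social scenario (equilibrium by ~20k ticks), 20 datasets per
panmictic scenario with the equilibrium fast start, 1000 conditional
replicates per locus everywhere (the procedure's own constant), and 100
datasets for the stationary-coalescent expansion share.  Full-scale
presets (100 replicates, 5×10⁵ ticks) are registered in
`experiments.PRESETS` and run unchanged via `run_scenario(name)`.

## 7. Known limitations and residual disagreements

* The social model matches the published demography closely (censuses
  ~600/~1246/~6090; RS complements fully occupied) but its genetic
  structure at 50 groups settles at F_ST ≈ 0.13–0.14 and He ≈ 0.2–0.33,
  and from there the inference stages measure what they measure.
  Spurious-expansion shares, measured at scale: 20.0% on θ=2 coalescent
  data (60/300 datasets; published 30%), ~50–60% monogamy, ~50%
  polygynandry and ~20% polygyny (published 27/32/38%), 16.7% haploid and
  ~30% diploid Wright–Fisher (published 37/29%); bottleneck shares stay at
  2–3% everywhere.  Social-scenario LD-Ne comes out of order 10²
  (published ≈ 30).  Three variants of the vacancy rules gave
  statistically indistinguishable structure, so the published combination
  — diversity preserved *and* contemporary Ne ~30 *and* only a mild
  expansion bias — implies a sharper separation between the local breeding
  scale and the metapopulation scale than the documented rules produce.
  The qualitative findings are robust in every variant:
  expansion-dominated false signals far above the nominal 5% in all
  mating systems, near-zero bottleneck calls, and Ne estimates far below
  census size.
* The polygynandry census is structurally ≈ 2× monogamy's (two breeding
  females per group): 1246 ± 1 measured, ~25% above the published
  "around 1000".
* The conditional-Heq rule is identified behaviorally (§3), not from a
  published algorithm listing; `first_passage` is provided for
  sensitivity analyses.
* Monogamy's RS complement at 50 groups is exactly 100 slots, so "RS
  above 100" is testable only as full occupancy (mean ≥ 97–99 with
  transient vacancies).
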