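# Methods

## The simulation model

`rdinvade` simulates a single autosomal marker locus with two alleles,
wild-type (WT) and the dominant Reindeer marker (Rd), in a closed
population with discrete, non-overlapping generations. An individual is a
sex plus a diploid genotype; internally a genotype is its WT-allele count
(0, 1, 2). The WT phenotype is expressed only by WT/WT homozygotes, so the
phenotype proportion the experimenters score equals the WT-homozygote
proportion the simulator tracks.

One replicate proceeds as follows.

1. **Founders (generation 0).** 50 Rd/Rd females, 40 Rd/Rd males and
   10 WT/WT males: 100 adults, 1:1 sex ratio, 10% WT, and no WT females —
   which is why WT homozygotes cannot exist among generation-1 adults and
   scoring begins at generation 2.
2. **Pairing.** Each generation fills a fixed number of mating slots equal
   to the female recruitment quota (230 by default). Mothers and fathers
   are sampled *with replacement* from the adults of each sex; sampling is
   genotype-weighted when the corresponding fitness component is active
   (see below), uniform otherwise.
3. **Reproduction.** Every pair produces exactly 52 offspring under
   Mendelian inheritance (each parent transmits a uniformly chosen allele,
   independently per offspring).
4. **Viability selection.** `floor(survival_fraction × n_offspring)`
   offspring survive (30% by default), sampled without replacement —
   genotype-weighted when the offspring component is active, a uniform
   thinning otherwise. Weighted sampling without replacement uses
   exponential sort keys (key = Exp(1)/weight, keep the k smallest), which
   is equivalent to successive draws with weight renormalisation and
   reduces exactly to uniform subsampling at equal weights.
5. **Recruitment.** Each survivor is assigned a sex by a fair coin; 230
   males and 230 females are then drawn uniformly without replacement into
   the next breeding population. If either sex cannot fill its quota the
   replicate raises an explicit demographic-failure error carrying the
   generation index — never a silent truncation. At the default
   parameters (≈3,588 survivors for 460 slots) failure is vanishingly
   unlikely.

**Selection.** The relative fitness of WT vs Rd genotypes is a single
parameter α ≥ 1. Class weights are Rd/Rd = 1, WT/WT = α and heterozygotes
intermediate — arithmetic mean (1+α)/2 by default, configurable to the
geometric mean √α. Normalised over a candidate pool these weights give the
sampling probabilities 1/(α+1) and α/(α+1) for an Rd/WT pair. The
advantage can act independently through three components: male reproductive
success (weighted father sampling), female reproductive success (weighted
mother sampling, active only from the parental generation index 1 onward —
founder females are all Rd, so a female advantage cannot act in the first
round of breeding), and offspring viability (weighted survival). The eight
on/off combinations are scenarios i (neutral) through viii (all three);
combined scenarios share one α across components.

### Choices the design left open

* **Mating slots per generation.** The breeding design fixes how many
  adults initiate each generation (230 of each sex), so we treat the slot
  count as a constant of the design: 230 female-anchored slots every
  generation, founders included, with mothers sampled with replacement.
  The alternative — one slot per founder female (50) in generation 0 —
  makes the low-survival sensitivity analysis infeasible: 50 pairs × 52
  offspring × 10% survival leaves 260 survivors, below the 460-adult
  recruitment quota, so every replicate would fail demographically at
  generation 1. With constant slots the offspring pool is 11,960 per
  generation and the 10% and 50% sensitivity settings run cleanly.
  Founder expectations are unchanged (mothers are exchangeable Rd/Rd
  females either way).
* **Survivor count rounding.** `floor` of the fraction; the design states
  a percentage, not a rounding rule.
* **Offspring sex.** Assigned independently, fair Bernoulli, at survival
  time.
* **Quantiles.** Grid summaries use linear-interpolation quantiles
  (numpy's default).
* **Seeding.** One master seed per run. Each replicate's stream is derived
  from (seed, scenario index, α, survival fraction, replicate index), so a
  replicate is reproducible in isolation, a shorter run reproduces a
  prefix of a longer one, and a full grid run is bit-reproducible.

## The scenario grid

The default grid is 1 neutral cell plus 7 scenarios × 4 α levels
(1.5, 2, 5, 10) = 29 cells at 30% survival, 500 replicates per cell, 8
generations per replicate. Sensitivity grids at 10% and 50% survival are
built the same way. Each cell is summarised per generation by the median,
the 5–95% quantiles and the mean of the WT-homozygote proportion across
replicates. A full default grid runs in about a minute on one CPU; the
test suite uses the full 500-replicate grid once (shared fixture) and
smaller grids elsewhere.

## Synthetic datasets

The package is exercised end-to-end on synthetic data with the statistical
structure of the two empirical assays; no external data are required.

**Invasion datasets** emulate the 24-population design (2 regimes × 3
lines × 4 replicate populations, generations 2–8). Each population is one
simulator trajectory under its regime's generative fitness scheme. The
defaults encode the scenario most consistent with the observed assay —
scenario viii (all components) with α = 2 for the Polyandry background and
α = 1.5 for Monogamy; these are generator defaults for producing
realistic-looking data, not inferences about real beetles. At each scored
generation a subsample size is drawn from a truncated normal with the
empirical mean (461) and range (167–586); only mean and range are
reported for the real assay, so the spread (sd = 70) is a modelling
choice. The scored WT count is a binomial draw of the subsample size
against the population's WT-homozygote proportion — the experimenters
score a phenotype-blind subsample of a larger adult pool, which the
460-adult simulated population stands in for. Optional line-level
heterogeneity (lognormal jitter on α per line) is available but off by
default. The generator never emits generations 0–1: under Rd dominance no
WT phenotype can be scored before generation 2.

**Fecundity datasets** emulate the five noncompetitive crosses: 45 Rd × Rd
pairs; 9 WT pairs per line per regime (54 total); and 21–24 pairs per line
per regime for WT male × Rd female (139), hybrid son × Rd female (138) and
Rd male × hybrid daughter (138). Counts are negative binomial with
group-specific means — 96 for Rd × Rd, 76 for WT × WT (both regimes share
one mean, so the regime contrast is null by construction, matching the
empirical finding), 96 for crosses with an Rd dam and 86 (the midpoint)
for the hybrid-daughter cross, the latter two being unreported and chosen
for plausibility. The NB size parameter k = 110 makes the Rd × Rd group SE
≈ 2 at n = 45 (matching the reported 96 ± 2); no dispersion is reported,
so k is calibrated to that SE. `k = inf` gives the Poisson limit.

## Analysis

* **Regime summaries.** Per regime × generation, the mean and SE of the
  12 population-level WT-phenotype proportions; the difference trajectory
  (Polyandry − Monogamy) and its argmax generation. On the packaged
  reference table (expanded to 12 identical populations per regime) the
  summary reproduces every printed mean exactly and the difference peaks
  at generation 5 (0.79 − 0.44 = 0.35 from the printed two-decimal means).
* **Permutation test.** The regime contrast is tested by permuting
  population regime labels *within line*, respecting the nested design.
  The statistic is the difference of regime means of per-population
  proportions averaged over generations. All label arrangements are
  enumerated exactly when their number does not exceed the requested
  permutation count; otherwise Monte Carlo with an add-one p-value. This
  is a distribution-free surface deliberately simpler than a
  negative-binomial mixed model, which would need the raw replicate data;
  the report labels it as such. Type-I calibration at nominal 0.05 is
  checked in the acceptance suite over 500 null datasets.
* **Scenario fit.** Each simulated cell's median trajectory is scored
  against an observed regime trajectory by RMSE over generations 2–8
  (equal weights; MAE available), and cells are ranked ascending. The
  distance is zero iff the trajectories coincide on generations 2–8, and
  the ranking is invariant to input order (ties broken by scenario label,
  then α). Fitting to regime means (not individual populations) mirrors
  how the observed and simulated trajectories are normally compared.

## What the tests show — and what they don't

The synthetic generators reproduce the *design* (counts, sampling ranges,
nesting) and first- and second-moment structure (group means, an SE-matched
overdispersion) of the empirical assays. They do not emulate line-level
genetic differentiation beyond the optional α jitter, temporal correlation
of subsample sizes, food-medium dynamics, or the gradual recombination
decoupling of the marker from its genetic background (fitness is fully
linked to the marker here, so for a given α the simulation overstates the
introgression rate in later generations). Passing tests therefore validate
the machinery and its calibration on data of the assumed structure, not
biological conclusions about real populations.

## Numerical notes and limitations

* Proportions are exact ratios of integer counts; no floating-point
  accumulation occurs inside a replicate.
* The permutation p-value is conservative by construction (add-one rule in
  Monte Carlo mode) and exact under enumeration.
* Scenario-fit distances are comparable only against one observed
  trajectory; ranks, not raw distances, are the interpretable output.
* Demographic failure is possible in principle for extreme configurations
  (tiny survival fractions with large quotas); it is raised, identified by
  grid cell, and propagated rather than patched.
* Heterozygote fitness is a one-parameter interpolation; true dominance of
  fitness (as opposed to the marker phenotype) is unknown and not jointly
  estimable from trajectory data of this shape.
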