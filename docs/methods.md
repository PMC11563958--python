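# Methods

## Founder genomes

Founder haplotypes come from a neutral coalescent with recombination
(msprime), one independent tree sequence per chromosome, under a
constant-size population. Defaults: 12 chromosomes of 1.20 Morgans and
3×10⁷ bp (uniform 4×10⁻⁸ Morgan/bp), mutation rate 2.5×10⁻⁸/bp with a
binary (0/1) mutation model, effective population size Ne = 60, and 80
diploid founders. A constant-size history is the simplest model
consistent with a single stated Ne; no demographic events are assumed.

From the segregating sites of each chromosome, 250 QTL and 100 markers
are chosen by snapping two disjoint even grids in genetic-map position
to the nearest unused sites. Grid placement realizes "equally/uniformly
distributed" loci while keeping QTL and panel disjoint — the
conservative reading of a genotyping panel that does not tag causal
loci. The site-frequency spectrum of the retained loci is the
coalescent's: strongly U-shaped at Ne = 60, which matters for the
allele-fixation accounting (see Limitations). After the founders there
is no mutation; all downstream variation is recombination and
segregation of founder alleles.

Meiosis uses a no-interference model: crossover counts per chromosome
are Poisson with mean equal to the map length (1.2), positions uniform
on the genetic map, and each chromosome starts from a uniformly chosen
parental haplotype. Two-locus recombination therefore follows Haldane's
map function, verified against closed forms in the test suite. The
gamete builder copies haplotype segments between breakpoints (a numba
kernel), so runtime scales with carried loci (4,200), not physical
genome size.

## Trait model

The genetic value of a line is

    GV = μ + Σ_q a_q x_q + w · Σ_q g_q x_q

with x the scaled dosage (homozygotes ±1, heterozygote 0). Additive
effects `a` are i.i.d. standard normal, then affinely rescaled so the
*founder-population* additive mean and variance are exactly μ = 0 and
σ²_A = 1. GEI effects `g` are rescaled the same way so the founder
variance of the genotype-specific slope Σ g·x equals σ²_GEI ∈ {0, 4, 8}.
The environmental covariate w ~ N(0,1) is drawn once per calendar year
and shared by every trial of that year; location structure enters only
through the error-variance division by plot count. With Var(w) = 1, the
across-population variance of the GEI deviation, averaged over years,
equals σ²_GEI.

Phenotypes are GV(w) plus a normal error. Error variances are anchored
once to the founder calibration, σ²_E = σ²_A(1−H²)/H²: row nurseries
(H² = 0.001, σ²_E = 999) and yield-trial plots (H² = 0.10, σ²_E = 9,
divided by locations×reps for trial means). They are never re-estimated
as variance erodes, so realized heritability declines over the cycles —
intended behavior. σ²_GEI is excluded from the H² denominator; the two
are independent knobs.

The tracked "true genetic value" of the performance indicators is the
main-effect value (w = 0); GEI enters selection only through phenotypes
and through GEBVs trained on GEI-contaminated trials.

## Genomic prediction

RR-BLUP: y = 1β + Zu + ε with Z the n×1,200 {−1,0,+1} marker matrix.
The variance components are estimated by REML on the spectral
decomposition of the intercept-projected ZZ′ (one eigendecomposition,
then a 1-D search over log λ on a grid of 81 points in [10⁻⁸, 10⁸]
refined by bounded minimization to 10⁻⁸). Effects follow from
u = Z′(ZZ′+λI)⁻¹(y−1β) with the GLS intercept; the identity with the
dense mixed-model equations is tested to 10⁻⁶ on random instances.
Degenerate inputs (constant y or constant markers) return a flagged
null model. Training phenotypes are per-line trial means; no location
fixed effects are fitted because the simulated trials have no location
main effect.

Within-cohort prediction trains on a 200-line estimation set (EST)
sampled from the 1,200 candidates with every family represented (one
line per family forced, remainder uniform). Between-cohort prediction
keeps a sliding window of the three most recent cohorts' EST data (600
lines; `TrainingPopulation.window` exposes the policy switch — the
alternative, unbounded accumulation, is not used because the stated
training size stays at 600). Its initial training population is the
last three burn-in Stage-1 trial samples, reusing their Stage-1
phenotypes rather than re-phenotyping.

## Breeding calendars

All calendars are declarative stage tables (`schedules.yaml`): per
cohort age, an ordered list of steps (SSD generations, within-family
nursery selection, trials, prediction, recycling). A new cohort is
crossed every year from the current 40 parents (30 random half-diallel
pairs, 240 F1 per cross), so the program runs parallel overlapping
cohorts and one cohort reaches the Stage-1 recycling point every year.
Parents selected in year t are first crossed in year t+1; a cohort
crossed in year t recycles at age A (4 for the 5-year calendars, 2 for
the 3-year, 1 for the 2-year), giving cycle length A+1 — the scheme's
name.

Stage flow (full scale): 30×240 = 7,200 lines exit RGA at F6/F4/F3
(5-/3-/2-year); marker-assisted selection is modeled as within-family
phenotypic selection at H² = 0.001 keeping 40 per family (1,200 lines);
seed amplification adds one selfing where scheduled and no selection;
Stage 1 evaluates/genotypes the 1,200; 30 lines advance to Stage 2
(4 locations × 2 reps). Stage 2 does not feed back into recycling.

Trial intensity at Stage 1 differs by criterion, and this choice is
load-bearing: the full 1,200 candidates only ever see a single-season,
single-location plot trial (the seed-amplification-stage trial), while
the 4-location × 2-rep MET is reserved for the 200-line EST and for
Stage 2. Phenotypic selection (baseline, burn-in) therefore operates at
accuracy ≈ 0.3, within-cohort GEBVs at ≈ 0.5–0.6 — which is what makes
genomic selection at unchanged cycle length outperform the phenotypic
baseline, and what produces the early rise of between-cohort accuracy
as noisy burn-in training data are replaced by MET EST data. Giving the
baseline a full MET on all 1,200 lines instead would invert the
baseline/5-year ordering.

The burn-in runs the 5-year calendar shapes with reduced pressure for
40 years: 80 founders, 100 crosses × 120 progeny, LST keeps 25 per
family (2,500), a single-location trial keeps 600, Stage 1 evaluates
the 600, Stage 2 the top 50; each year 80 parents are truncation-
selected from the union of that year's Stage-1 and Stage-2 trial
populations. The final Stage-1 cohort is the base population (year 0);
every scheme branches from a bit-identical copy of the full pipeline
state. Burn-in cohorts still in flight finish under burn-in rules and
provide the recycling populations of the first A years; their parents
are selected phenotypically. Scheme year-1 parents are the top 40 of
the base population on its Stage-1 phenotypes.

## Experiment orchestration and seeding

A replicate runs one burn-in per GEI level (the founder genome and
additive effects are shared across GEI levels; g is re-scaled) and
branches every scheme from the same state, so scheme contrasts are
paired within replicate. Burn-ins are re-run per replicate so replicate
spread includes base-population sampling. All randomness flows from
`numpy.random.SeedSequence([master_seed, replicate, gei, scheme])`;
identical configuration and seed reproduce outputs byte-for-byte, and
per-replicate part files allow interrupted grids to resume.

## Problem sizes for the shipped reproductions

The acceptance script uses 10 replicates with the nursery expansion
scaled to one third (80 progeny per cross in the schemes, 40 in the
burn-in); every selection endpoint — Stage-1 size 1,200 (600 in the
burn-in), crosses, parents, training sets, trial dimensions, QTL and
marker counts — stays at full program size, so all selection
intensities are preserved. The only stage the scaling weakens is the
within-family nursery selection, which operates at H² = 0.001 and is
nearly random by design. The test suite's end-to-end checks use scale
0.25 with 3 replicates. Full-scale and scaled runs agree on gain
slopes within replicate noise on the schemes checked.

## Numerical choices

Truncation selection breaks ties by ascending line id (deterministic,
seed-independent). Genetic values accumulate in float64 via a numba
kernel with a fixed summation order, so results are machine-exact
reproducible. The REML search bounds λ in [10⁻⁸, 10⁸]; at the bounds the
model degrades gracefully toward OLS / the null model. Burn-in Stage-2
populations are kept one extra year so same-year parent pooling can see
them.

## What the generator does and does not emulate

Simulated data share the structure the scheme comparison needs:
realistic linkage disequilibrium from a small-Ne coalescent, family
structure from a closed 40-parent crossing block, heritability-anchored
trial noise, and a single-covariate GEI. They do not include mutation
after the founders, dominance or epistasis (of limited relevance for
inbred lines), multi-trait selection, location main effects or
structured (compound-symmetry/unstructured) GEI covariance, seasonal
(sub-year) timing, or operational costs. Passing tests therefore speak
to the closed-system dynamics of cycle length, prediction mode and GEI
level — not to absolute yields in any real target population of
environments.

## Known limitations

* With Ne = 60 the founder favorable-allele spectrum is strongly
  U-shaped: ~30% of QTL start above 0.90 frequency. After the burn-in
  this yields ~35% nearly-fixed favorable alleles, which the
  allele-fate indicators inherit as a higher starting point than a
  flatter founder spectrum would give; the published base-population
  figure is lower (≈25%), suggesting the original founder simulation
  carried a flatter spectrum than a constant-size Ne = 60 coalescent.
* Realized gains of the fast within-cohort schemes (2-year-WP, 3-year)
  track the breeder's-equation prediction: per-cycle response times
  1/L, damped by variance depletion. The published comparison shows a
  stronger compression of short-cycle gains than this mechanism
  produces here, so the simulated 2-year-WP/3-year advantage over the
  5-year scheme is larger than published even though baseline, 5-year
  and between-cohort gains, accuracies, variance-depletion and
  fixation levels agree. The compression mechanism (e.g. season-level
  recycling delays) is not specified and is deliberately not tuned for.
* Accuracy for the baseline is the phenotype–GV correlation of the
  single-plot trial; the published accuracy range is reported for
  genomic predictions only.
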