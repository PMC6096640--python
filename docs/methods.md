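# Methods

`twopartsim` simulates complete inbred-line breeding programs to compare
how the population improvement component of a two-part program should be
managed: by truncation selection or by optimal cross selection (OCS).
This note records the models, the defaults and why they are what they
are, the numerical choices, and what the simulator does and does not
capture.

## Genome, meiosis, founders

Individuals are diploid with biallelic loci on `n_chr` chromosomes
(default 10), each 1 Morgan long and carrying 100 causal and 100 marker
loci at alternating, evenly spaced positions.  Meiosis follows the
Haldane model: crossover counts per chromosome are Poisson with mean
equal to the map length, chiasma positions are uniform and there is no
interference.  Doubled-haploid (DH) production doubles one recombinant
gamete, giving a fully homozygous line in one step.

Founders are built in two stages: per-locus allele frequencies are drawn
from U(0.05, 0.95) and haplotypes as independent Bernoulli draws, then
the population (default 100 individuals) undergoes 10 generations of
random mating (selfing excluded) so that linkage disequilibrium builds up
at the map scale — without LD, marker-based prediction and coancestry
would see nothing.  Loci whose realised minor allele frequency falls
below 0.05 are re-drawn; this floor guarantees every locus segregates, at
the price of erasing LD at the re-drawn loci only.  Coalescent founder
simulation is deliberately out of scope; the two-stage construction is
self-contained and seedable.

The trait is strictly additive: allele substitution effects at the causal
loci are N(0, 1) rescaled so the founder *genic variance*
`2 Σ p_i (1 − p_i) α_i²` equals 1.  Genic variance depends only on allele
frequencies, which is what makes inbred DH cohorts and outbred
population-improvement germplasm comparable on one diversity scale.
Dominance, epistasis and genotype-by-environment interaction are not
modelled.

## Phenotypes and the trial pipeline

The product development pipeline is a six-stage yearly conveyor: cross →
DH → headrow → preliminary → advanced → elite.  Each stage phenotype is
the true genetic value plus Gaussian noise with variance
`(1 − h²)/h²` (anchored at the initial genic variance of 1), with
heritabilities rising by stage: headrow 0.1, preliminary 0.2, advanced
0.4, elite 0.5.  These are configurable conventions, chosen to mimic the
increase in replication from visual single-plant scores to multi-location
yield trials.  Desk-scale stage sizes are 16 crosses × 20 DH → 320
headrows → 50 preliminary → 12 advanced → 4 elite per year.  A
`full_scale()` preset mirrors a full-size program whose trial stages
contribute 1040 genotyped-and-phenotyped lines per year (1000 preliminary
+ 30 advanced + 10 elite), i.e. 3120 records over the three-year window
that initiates the training set.

## Genomic prediction

The prediction model is the standard random-marker ridge (RR-BLUP) with
an intercept as the only fixed effect and *heterogeneous error variance*:
each record carries a weight equal to its effective replication (headrow
1, preliminary 2, advanced 4, elite 8), so `var(e_j) = σ²_e / w_j`.  The
variance ratio `λ = σ²_e/σ²_β` is estimated by REML: the intercept is
absorbed by weighted centring, the centred weighted cross-product matrix
is eigendecomposed once, and the profiled criterion is minimised over
log λ (bounded scalar search, tolerance 1e-8).  The training set is
append-only and keeps running cross-products, so yearly retraining costs
one m × m eigendecomposition regardless of how many records have
accumulated.  Records are never discarded and the model is retrained once
per simulated year.

A note on weighting: replicating every record k times at weight w/k
leaves the ridge solution unchanged at any fixed λ (the sufficient
statistics are identical), but the REML ratio itself shifts slightly
because its degrees-of-freedom term counts records; tests pin both
behaviours.

## Optimal cross selection

Candidates are split into female and male pools (hermaphroditic plants
are alternated by GEBV rank so the pools are balanced).  Coancestry is
identity-by-state from markers, `C = ½(1 + XX'/n_m)` with `X = M − 1`.
A plan assigns each candidate an integer number of crosses 0–4 whose
pool totals equal `n_c`; with `x = n/(2 n_c)` the plan's expected gain is
`x'a` and its group coancestry (expected next-generation inbreeding)
`x'Cx`.

The gain/diversity dial is a penalty degree θ on the normalised plane
spanned by two anchor solutions computed under identical constraints:
S0, the maximal-gain plan (computed exactly — the objective is linear in
the contributions, so filling the per-parent cap down the breeding-value
ranking is optimal) and S90, the minimal-coancestry plan (found by the
evolutionary search).  Writing ā′ and c̄′ for gain and coancestry
normalised so S0 = (1, 1) and S90 = (0, 0), an interior degree maximises

    fitness = ā′ − 10 · max(0, c̄′ − (1 − sin θ))

and the achieved degree of any plan is `arcsin(1 − c̄′)`.  The
quarter-circle target `1 − sin θ` reproduces both endpoints (θ = 0°
returns S0, θ = 90° returns S90 — at the exact endpoints the single
objectives are optimised directly) and allocates protection the way the
dial is used in practice: already at moderate degrees most of the
coancestry span is forbidden.  A cosine target (`cos θ`) was evaluated
and rejected: it leaves so much of the span available at typical degrees
that the optimised program loses both gain and diversity to plain
large-parent truncation, defeating the method's purpose.

The search is differential evolution (rand/1/bin, F = 0.7, CR = 0.9,
population 40, up to 1000 generations with early stop after 200 stagnant
ones; the in-simulation configuration is scaled down to population 20 and
120 generations) over a real-valued score per candidate in [0, 1].
Decoding is rank-based and always feasible: within each pool, candidates
are taken in descending score order and the score magnitude sets the
contribution (`ceil(4s)` clamped to 1–4 and to the remaining slots).
Two refinements matter in practice:

* the initial population is seeded with four rank-structured genotypes
  (cap-filled truncation through equal single-cross spread across the top
  parents); on problems with hundreds of candidates an unseeded random
  population essentially never finds structured contribution patterns;
* on problems with ≤ 40 candidates the DE result is polished to a depth-2
  local optimum over within-pool unit moves (single moves, then pairs),
  which lifts the search off the decode's plateaus — with it the
  enumerable test instances are solved exactly in effectively every seed.

Mate allocation is separated from contribution optimisation because gain
and group coancestry are pairing-invariant: contributions are expanded
into crosses by greedily pairing the female with the most remaining
crosses to the least related available male, avoiding duplicate pairs
(duplicates are emitted only when structurally forced, e.g. the
maximal-gain plan with `n_c ≤ 4` repeats the single best pair).  This
lowers progeny inbreeding at zero cost to the optimised objectives.

Truncation plans take the top parents by GEBV (ties broken by id),
alternate them into pools by rank, give every parent an equal share of
crosses (±1) and pair the pools at random without duplicate pairs.

## Breeding programs

All programs share a 20-year burn-in under phenotypic selection, after
which scenarios branch from a deep copy of the same state — including the
random stream, so paired scenarios run under common random numbers.
Standardisation constants (genetic mean and SD, genic SD) are fixed at
the final burn-in year on that year's DH cohort; all later gains are in
burn-in genetic SD units and genic SDs are relative to that year.
Metrics are always computed on the year's new DH lines, before any
headrow selection, so every program is measured on the same material.

Conventional variants: `conv` selects parents by phenotype from the
preliminary/advanced/elite cohorts; `convp` and `convh` select parents
(and the corresponding stage advancement) by GEBV at the preliminary or
headrow stage respectively, shortening the effective cycle.

The two-part program runs k population-improvement cycles per year
(k = 1–6).  The per-cycle budget splits a fixed yearly envelope of 64
crosses / 640 genotyped candidates: `crosses = ceil(64/k)`,
`candidates = ceil(640/k)`, minimum parents `2·ceil(crosses/4)`, maximum
`2·crosses` (the unconstrained mode instead repeats the full-size cycle
k times).  Each cycle predicts GEBVs with the current model, builds a
plan (truncation with the minimum parents for TS, the maximum for TS+,
or OCS at the scenario's penalty degrees) and crosses, distributing the
candidate budget as evenly as possible across crosses.  Once per year the
newest PD doubled haploids join the candidate pool, the best PI germplasm
(top `2·pd_crosses` candidates by GEBV, one cross each) seeds the PD
crossing block, the model is retrained, and the PD conveyor advances.
The yearly metric population pools the new PD DH cohort with a direct DH
sample of the current PI germplasm (default 100 lines), covering both
kinds of doubled haploids the program produces.

## Comparison metrics

* Standardised gain: `(v − μ_ref)/σ_ref` with the burn-in reference
  constants.
* Realised effective population size: genic variance decays as
  `σ²_{t+1} = σ²_t (1 − ΔC)`, so ΔC is recovered by a log-link gamma
  regression of genic variance on year (`ΔC = 1 − exp(β)`) and
  `Ne = 1/(2ΔC)`.  A non-decaying series makes Ne undefined (reported as
  missing); years after a program has run its genic variance to exactly
  zero are excluded from the fit.  Note the drift calibration: under
  Wright–Fisher random mating genic variance decays at `1/(2N)`, so a
  neutral population of N individuals measures `Ne ≈ N`.
* Conversion efficiency: the slope of standardised gain on relative genic
  SD lost (`x_t = 1 − σ_t/σ_ref`), fitted by Huber M-estimation (tuning
  constant 1.345, IRLS, ≤ 50 iterations) after dropping points that
  exactly repeat their predecessor (a program idling at its selection
  limit).  A perfectly collinear trajectory short-circuits to OLS, whose
  solution is exact there, because the robust scale estimate degenerates
  at zero residuals.  The worked intuition: a trajectory from (0, 0) to
  (10, 0.4) converts 0.4 genic SD into 10 SD of gain — efficiency 25.
* Replicate aggregation: mean and normal-approximation 95% CI
  (±1.96 SE).

## The standard comparison study

`twopartsim.study.run_comparison` is the package's headline experiment
and what `scripts/acceptance.py` re-runs: desk-scale conditions
(10 chromosomes × 200 loci, 100 founders), ten replicates of a 20-year
burn-in plus 10 evaluation years, scenarios {conventional, TS, TS+, OCS}
with cycle counts {1, 4, 6} under constrained budgets.  OCS runs two
kinds of arms.  At four cycles, a mild (20°) and a moderate (45°)
penalty; the reported four-cycle OCS gain takes the better degree,
mirroring the practice of reporting the penalty that maximises long-term
gain, while the 45° arm is the diversity-retention comparison point.
Across the cycle grid {1, 4, 6} OCS runs at a strong penalty (60°) under
which the diversity budget does not bind within the ten-year horizon:
this is the arm on which the cycle-count response of a diversity-managed
program is measured.  The compressed desk-scale dynamics need more
protection per cycle than a full-size program, just as the full-size
optimum degrees themselves rise with the cycle count; at milder degrees
the six-cycle arm begins rationing diversity within the horizon and its
endpoint gain drops below the four-cycle arm, which says something about
the horizon, not about cycling.  Problem sizes were chosen so the
full study runs on one CPU in roughly ten minutes; the qualitative
structure (gain orderings, diversity retention, the efficiency–Ne
association) is the study's output, not the full-size program's absolute
numbers, which would require cluster-scale replicates of 20 evaluation
years at the `full_scale` preset.

## What the synthetic data does not capture

Founders are not coalescent samples, so the site-frequency spectrum and
long-range LD of real elite germplasm are only caricatured; mutation is
absent, so diversity can only be spent; the trait is purely additive with
equal-variance effects; trial phenotypes are Gaussian with fixed
stage-wise error variances and no year or location effects; and the
desk-scale populations drift much faster than a full-size program, which
compresses 20 years of full-scale dynamics into roughly 10.  Passing
tests therefore demonstrate correctness of the machinery and the
direction and ordering of effects, not calibrated absolute gains for any
real breeding program.

## Numerical choices and degenerate inputs

Ties in any ranking break by id for determinism.  All randomness flows
from one root seed (replicate i uses root + i; module streams are spawned
with `numpy` seed sequences, and scenario branches inherit the burn-in
stream for common random numbers).  REML's λ search is bounded to
e^[−18, 18]; a training set with no phenotypic variation raises an
estimation error and the simulation keeps the previous year's model.
Constant vectors make prediction accuracy undefined (reported as NaN,
never 0).  The gamma GLM uses IRLS tolerance 1e-12, so exact geometric
decays are inverted to ≈ 1e-10.
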