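# Methods

`breedsim` is a simulation study of genomic-selection (GS) calibration
across breeding generations: how reliably can marker effects estimated in
one population predict the true genetic values of later generations
advanced by self-pollination, random mating or hybridization, and how much
does pooling generations into a multigenerational training set recover?

## Genome and populations

The simulated genome is diploid with 10 linkage groups of 101 biallelic
markers at 1 cM spacing (1,010 markers, 1,000 cM).  Two fully divergent
inbred founders (all-1 vs all-0) are crossed; the F₁ is selfed to give the
F₂ base population (default N = 500), in per-locus Hardy–Weinberg
proportions with all disequilibrium due to linkage.  Four advancement
generations are produced per mating system:

* **selfing** (S₁..S₄): one selfed offspring per parent, which keeps N
  constant, removes family-size variance, and halves heterozygosity each
  generation;
* **random mating** (A₁..A₄): two distinct parents per offspring, drawn
  uniformly with replacement, self-fertilisation excluded;
* **hybridization/backcross** (Bc₁..Bc₄), see below.

Meiosis uses the Haldane mapping function, `c = (1 − exp(−2d/100))/2` for
`d` cM, applied per adjacent interval with no interference, and free
recombination between groups.

### Transmission modes

Three transmission modes are provided, because the study this package
replays cannot be reproduced by linked meiosis:

* `meiosis` — linked transmission as above.  This is the biologically
  standard model and the `popsim`-level default.  Under it, selfing and
  backcrossing conserve most gametic LD: an F₂-trained model still predicts
  S₄ with reliability ≈ 0.73, and the adjacent-marker r² stays near
  (1 − 2c)² ≈ 0.96.
* `independent_loci` — every locus is transmitted independently (free
  recombination between all markers); the map shapes only the F₂ founding.
  Single-locus genotype dynamics (heterozygosity decay, allele-frequency
  drift) still follow the mating system, but gametic disequilibrium halves
  every generation under every system.  This is the regime implied by the
  original study's results — its LD erodes strongly even under selfing,
  and its reliability tables (F₂ in-sample 0.81 falling to 0.51 by S₄)
  match this mode closely — so it is the `strategies`-level default.
* `allele_resampling` (random mating only) — offspring haplotypes drawn
  locus-by-locus from Bernoulli(current allele frequency).  Destroys all
  LD *and all family structure* in one generation; the next generation's
  mean r² equals the 1/(2N) independence baseline.

Passing tests under `independent_loci` therefore shows fidelity to the
replayed study's advancement regime, not to linked meiosis; real breeding
data on a dense map behaves like `meiosis`, under which cross-generation
reliabilities are substantially higher than the tables reproduced here.

### Backcross scheme

The hybridization series is ambiguous in the source material, and no
classic recurrent chain reproduces its published behaviour (reliability
*rises* with continued backcrossing; the first generation is anomalously
unpredictable in-sample).  Two schemes are implemented:

* `f2_hybrid` (default): Bc_n crosses generation n−1 of the selfing
  series (S₀ = F₂) back to the F₂ parent population, so every cohort is
  half fresh F₂ gametes and the series never drifts far from the training
  population.  This reproduces the published strategy-1 (≈ 0.50) and
  strategy-2 (≈ 0.46) backcross block averages.
* `recurrent_chain`: the classic Bc_n = Bc_{n−1} × recurrent parent, with
  the recurrent parent configurable as the F₁ genotype, the F₂ population
  (a random recurrent individual per offspring), or either inbred founder.

## Trait model

20 QTL (2 per group, placed at the markers nearest 25% and 75% of each
group span — 25 and 75 cM on the default map) control the trait.  Locus j
carries weight `p_j = C(19, j−1)/2^19` (symmetric binomial, so a few
central loci dominate), assigned in genome order.  The genetic value is

    G_i = μ + Σ_j a_j·score_ij + Σ_j d_j·het_ij

with `a_j = p_j·a`, `d_j = (d/a)·a_j`, score +1/0/−1 for the favourable
homozygote/heterozygote/other homozygote, and defaults μ = 0, a = 1 (so
G ∈ [−1, +1] for d/a ≤ 1).  QTL genotypes are included among the scored
markers by default (`hidden_qtl=True` removes them from the panel).

Phenotypes are `P = G + E`, `E ~ N(0, σ²e)` with
`σ²e = σ²g(1 − h²)/h²`.  σ²g is the *empirical* variance of G in the
phenotyped cohort — on a linked map the F₂ value exceeds the unlinked
closed form `Σ_j (a_j²/2 + d_j²/4)` because same-group QTL covary; the
closed form is available for comparison.  Two noise conventions are
provided: `per_population` (default) recalibrates σ²e from each cohort's
own realised genetic variance, so every generation is phenotyped at the
target h² — the convention the replayed study uses ("genetic variance
defined for each population"), visible in its in-sample reliabilities
staying flat across selfing generations even though inbreeding inflates
genetic variance; `f2_fixed` sets σ²e once from the replicate's F₂ and
holds the environment constant while h² drifts.  The scenario grid is
d/a ∈ {0, 0.5, 1} × h² ∈ {0.30, 0.70}, six architectures scored on the
same genotypes within a replicate.

## Additive-dominance G-BLUP

The model is `y = Xb + u_a + u_d + e`, intercept-only X, with
`u_a ~ N(0, Ga σ²a)`, `u_d ~ N(0, Gd σ²d)`, `e ~ N(0, I σ²e)`.  Marker
codings (dosages 2/1/0 at training allele frequency p, q = 1 − p):

    W: 2−2p, 1−2p, −2p          S: −2q², 2pq, −2p²

with `Ga = WW′/Σ2pq` and `Gd = SS′/Σ(2pq)²`, monomorphic markers
zero-coded and excluded from the denominators.  W is exactly
column-centred at the observed frequency; S centres only in HWE
expectation.  The dominance term is always in the model, including d = 0
scenarios.

Variance components are estimated by REML.  Two algorithms share one
driver: EM (monotone restricted likelihood, the reference algorithm, but
sublinear near a zero boundary) and average-information (AI) with
step-halving and an EM fallback whenever an AI step would decrease the
likelihood.  Components are floored at 1e−8 × var(y); convergence is the
largest parameter change relative to total variance < 1e−6 (max 500
iterations; non-convergence is flagged, not fatal).  The strategy runners
use AI (training sets reach n = 2000; EM needs hundreds of iterations, AI
under a dozen).

Marker effects are backsolved from the equivalent ridge (RR-BLUP) model:
`m̂_a = σ²ma W′V⁻¹(y − Xb̂)` with `σ²ma = σ²a/Σ2pq` (likewise dominance),
which equals the explicit mixed-model-equation solution; an explicit MME
solver exists as an independent route and is cross-checked in the tests.
Predictions for new individuals are `W_v m̂_a + S_v m̂_d` with the
validation genotypes coded at **training** allele frequencies — required
for coherent effect transfer across generations.  Reliability is the
squared Pearson correlation between predicted total genomic value and the
true simulated G.

## Calibration strategies

1. **F₂ training**: fit on the F₂, validate in-sample and on every
   advanced generation.
2. **Contemporary/outdated**: fit on generation n, validate on n..4 of the
   same system; the diagonal is in-sample (the same individuals train and
   validate — no holdout).
3. **Multigenerational**: pool F₂ with the first k generations
   (k = 1, 2, 3 → 1000, 1500, 2000 individuals; one common intercept, no
   generation effect) and validate on generations k..4.  Pooled allele
   frequencies code both training and validation.

Tables aggregate mean ± SD over replicates (default 10); block averages
are cell-replicate means averaged over cells.

## LD measurement

The primary r² estimator uses the observed 2N phased gametes:
`D = f(AB) − f(A)f(B)`, `r² = D²/(p_A q_A p_B q_B)`.  An EM estimator over
the double-heterozygote phase ambiguity handles unphased dosages (tol
1e−8, max 1000 iterations) and equals the phased estimator exactly when no
double heterozygotes occur.  Summaries are within-group only, by exact cM
distance; pairs with a fixed locus are skipped and counted.

## Numerical and design choices

* Seeds: one master seed fans out through
  `SeedSequence(master, spawn_key=(replicate, stage, architecture, item))`,
  so adding systems or architectures never shifts existing streams; a
  saved config + seed reproduces every output byte-for-byte.
* Genotypes are shared across the six architectures within a replicate
  (the same populations scored for six traits); environmental noise gets
  architecture-specific streams.
* Reliability is undefined (an error) for constant prediction or truth
  vectors rather than silently 0.
* Degenerate inputs: all-monomorphic marker panels and zero-variance
  phenotype vectors raise; empty populations cannot be advanced.

## Problem sizes used by the test suite and acceptance script

The reproduction runs use the full study conditions: 1,010 markers,
N = 500 cohorts, h² = 0.30, 10 replicates (ordering checks for the
random-mating series use 5 replicates; the gaps they test are several
times the replicate SD).  Unit and property tests use reduced genomes
(1–3 groups, 2–33 markers, N ≤ 500) with Monte-Carlo tolerances set from
binomial error at those sizes.

## Known limitations

* No mutation, selection, variable census size, crossover interference,
  sex chromosomes, epistasis or QTL×E; single trait per architecture.
* The `independent_loci` mode and `f2_hybrid` scheme are reconstructions
  of an undocumented simulator; the published backcross multigenerational
  block average (0.71) remains above what any implemented interpretation
  produces (≈ 0.59), and the published random-mating series sits between
  the `independent_loci` and `allele_resampling` regimes.
* EM-REML near a zero variance component converges sublinearly; use AI
  (default in the runners) when the point estimate at the boundary
  matters.
* In-sample reliabilities quoted for strategies 2–3 involve no holdout;
  they measure shrinkage quality, not out-of-sample generalisation.
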