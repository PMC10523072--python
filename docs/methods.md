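# Methods

`floralsync` analyses whether seasonal adjustment of sex allocation in a
monoecious, synchronously protogynous clonal plant translates into realized
siring success. The chain has five scientific stages — synthetic-population
simulation, clone assignment, fractional paternity, mating-opportunity
metrics, and seasonal models — each usable on its own tables.

## The biological model the simulator encodes

The motivating system is a single isolated stand of an emergent clonal
aquatic (about 25 × 60 m, flowering over Julian days 199–240). Its key
features, all reproduced by the generator:

* **Clonal structure.** Genets (multilocus lineages, MLLs) comprise 1–35
  ramets; roughly 40% of genets are singletons and the mean genet holds
  ~5.6 ramets. The genet-size law is a two-component mixture: a point mass
  at one ramet (probability `singleton_prob = 0.40`) and `2 + NegBin(size
  0.7, mean 6.63)` otherwise, truncated at 35. A single zero-truncated
  negative binomial cannot satisfy both the 40% singleton share and the
  observed mean size, which is why the mixture is used. Genet centres are
  uniform on the arena; ramets scatter around their centre with a 2 m
  Gaussian SD (stolon growth), so clones form patches.
* **Synchronous protogyny.** Each ramet carries one inflorescence whose
  female flowers all open over the first 1–2 days, followed by its male
  flowers staggered over the next `male_stagger_days` (default 4). Every
  flower is open exactly one day, so an inflorescence is functionally
  unisexual on any day and within-ramet selfing is structurally
  impossible; geitonogamous selfing between ramets of one genet remains
  possible.
* **Phenology.** First-flowering days follow a Beta(5, 2) law scaled onto
  the season: very few inflorescences open in the first ~12 days and the
  population flowering peak falls in the last third of the season.
* **Seasonal sex allocation.** The expected logit male share of an
  inflorescence is a polynomial in its (scaled) first-flowering day,
  default `0.45 − 1.4·z`: early inflorescences are male-biased, late ones
  female-biased — the sex-allocation pattern the trend model is meant to
  detect. Total flowers per inflorescence are Poisson-lognormal (mean 10,
  log-SD 0.45); male counts are binomial in the total at the day-specific
  male share.
* **Mating.** On each day, every open female flower draws its pollen donor
  among ramets with open male flowers that day with weight
  `N_male × exp(−d / kernel_scale)`. `kernel_scale = None` (the default)
  is spatially uniform mating — mating exactly proportional to male-flower
  share, the regime in which the pollen-transfer-opportunity index should
  predict siring. `kernel_scale = 0.5 m` is the strong-spatial-restriction
  scenario: near-neighbour pollination on a 25 × 60 m arena, which raises
  geitonogamous selfing to ~0.3 (within the 0.13–0.63 range reported
  across monoecious stands of this species) and is the regime in which the
  PTO–siring association degrades.
* **Genotypes.** Seven codominant loci, 15 alleles each, frequencies drawn
  from a symmetric Dirichlet (concentration 1). Each genet's genotype is a
  Hardy–Weinberg draw; non-founder ramets mutate at rate
  `somatic_mlg_rate = 0.05` by one allele at one locus (the founder always
  keeps the genet genotype, so every variant stays one allelic step from
  an observed reference). Observed ramet and seed tables add per-allele
  mistyping (`genotyping_error = 0.01`, replacement by a frequency-weighted
  random allele) and optional per-locus missingness (default 0). Seed
  genotypes are Mendelian from the true parental genotypes before noise.
  A fraction `seed_sample_fraction = 0.095` of pollinated flowers is
  genotyped, yielding ~350–500 seeds per season.

What the generator does **not** emulate: pollinator behaviour and
display-size effects on visitation, flower-position effects within
inflorescences, seed abortion/maturation failure, and year-to-year corm
dynamics. Passing tests therefore demonstrate correctness of the analysis
chain under proportional (or distance-damped proportional) mating with
known truth — not that real populations mate this way.

## Clone assignment

Ramets with identical allele calls and identical missingness form one
multilocus genotype (MLG). MLGs are clustered into multilocus lineages by
single linkage (transitive closure) over the graph joining MLG pairs whose
total allelic distance is ≤ 1. Distance is summed over loci scored in
both genotypes, with per-locus distance `2 − |multiset intersection|`.
The closure rule (rather than complete linkage) is chosen because somatic
variants and single mistyped alleles each sit one step from the clone's
reference genotype and should be absorbed regardless of their mutual
distance. Thresholds are configurable (`max_diff`); labels are canonical
(numbered by smallest member ramet id), so row order never changes the
partition.

## Fractional paternity

Mothers are known for every seed. Candidate sires are the distinct MLGs
(optionally restricted per seed to MLGs with open male flowers on the
seed's pollination day, which is both faster and biologically required).
The per-locus likelihood of candidate `c` is the mistyping mixture

    L = (1 − ε) · T(offspring | mother, c) + ε · P_HW(offspring)

with `T` the Mendelian transition probability (average over the four
gamete pairs) and `P_HW` the Hardy–Weinberg genotype probability at the
estimated allele frequencies (one representative per clone, so large
genets do not bias the estimate). Missing loci are uninformative; maternal
incompatibilities are softened by the same mixture instead of vetoing all
candidates. Posteriors multiply locus likelihoods with a uniform prior
(an optional UNSAMPLED-father class integrates the paternal gamete over
the allele pool; off by default since the population is closed), are
normalized, and MLG mass is summed per MLL. Posterior mass below
`min_pi = 0.01` is discarded and the remainder renormalized — mirroring
the floor below which parentage software does not report candidates, and
preventing vanishing probabilities from inflating the siring sample with
pseudo-sires. ε defaults to 0.01 per locus; no per-locus error estimation
from replicates is attempted.

## Mating metrics

For ramet *j* on day *k*: `f_j = N_j^m / Σ_{l≠j} N_l^m` (share of open
male flowers, self-ramet excluded from the denominator) and
`K_jk = f_j × Σ_{i∉g(j)} N_i^f` (times open female flowers on all ramets
*outside j's genet* — the asymmetry, ramet-level in the fraction but
genet-level in the female sum, is deliberate and matches the index's
definition). When one ramet holds every open male flower, the fraction's
denominator is zero; the sole donor gets `f = 1` (its opportunity is all
available female flowers — the natural monopoly limit), flagged
`sole_donor` in the output. Genet-day PTO sums `K_jk` over the genet's
ramets; the season total sums over days. Both the genet-level and
ramet-level tables are emitted, and only genet-days on which the genet had
any open flower count as observations.

Realized siring success per MLL per day sums posterior paternity mass over
seeds pollinated that day, after dropping mass on the seed's own maternal
MLL (outcross siring only, unless `exclude_selfed=False`). A seed's
pollination day is the day its maternal flower was open (recorded in the
seed table).

## Seasonal models

Three models, exposed as Model classes whose `fit()` returns a Results
object with `summary()`:

1. **Sex-allocation trend** — binomial (logit) response `n_male` of
   `n_total` per inflorescence against first-flowering day.
2. **PTO trend** — Gaussian response, daily genet-level PTO against day.
3. **Siring model** — linear mixed model of log10 daily siring success on
   siring date and PTO (each alone and together, stepwise by AIC), MLL
   random intercept, via statsmodels `MixedLM` (ML, so AICs are
   comparable). Only genet-days with positive outcross siring mass enter;
   an offset alternative `log10(RS + c)` is available behind a flag.

The two trend models use an in-package penalized additive engine: a
10-basis B-spline of day (statsmodels' B-spline basis and difference
penalty) plus a ridge-penalized block of MLL indicator columns — the
standard mixed-model representation of a random intercept, whose
smoothing parameter maps to the variance component `σ_b² = φ/λ`. Fitting
is penalized IRLS; smoothing parameters minimize GCV (Gaussian) or UBRE
(binomial) via Nelder-Mead on log-λ with warm-started inner iterations.
Reported per fit: intercept ± s.e. on the link scale, smooth-term
effective degrees of freedom (trace of the block influence matrix), an
approximate Wald test of the smooth block (rank-truncated covariance,
χ² for binomial, F for Gaussian), conditional AIC (deviance-based, using
total edf), the random-intercept variance, and the same quantities for
the linear-counterpart fit run through the same machinery so the
AIC comparison is internally consistent. The nested
inflorescence-within-MLL random effect is dropped automatically — with
one record per inflorescence it is unidentifiable — and flagged in the
results.

Numerical choices worth knowing:

* Smoothness search is bounded (≤ 60 function evaluations per λ); fits
  are deterministic and bit-reproducible for fixed input.
* The smooth-term p-value uses df = rounded block edf; it is approximate
  in the usual mixed-GAM way and validated against mgcv on fixtures
  (same population curve, r > 0.99), not identical to any one engine.
* The siring model's denominator df use the between-within (containment)
  rule `n − #groups − #slopes` rather than a Satterthwaite approximation;
  p-values on ~100+ df are insensitive to this choice, but exact df will
  differ from REML-Satterthwaite software.
* When the MLL variance in the siring model hits the zero boundary (or
  the Hessian is singular there), the model *is* the fixed-effects model:
  the fit falls back to OLS, reports `re_variance = 0`, and counts one
  fewer parameter in AIC. This is flagged `re_boundary`.
* Zero-division conventions and degenerate inputs (no donors on a day, no
  female flowers, empty paternity) yield zeros or empty tables, never
  exceptions; genuinely invalid inputs (negative counts, single allele
  calls, unknown mothers) raise validation errors naming file and row.

## Problem sizes and test design

Unit tests run on reduced populations (40–80 genets) with the same
biology; replicated pattern checks use the full default population
(169 genets, ~950 ramets, ~40-day season) over 20 seeds, and the
acceptance script uses the defaults plus a 10-replicate two-kernel
comparison. These sizes were chosen to estimate detection rates stably
while keeping a complete run in minutes on one core.

## Known limitations

* The paternity likelihood treats seeds independently given the known
  mother; full sibship reconstruction (and per-seed confidence categories
  à la Δ-criterion software) is out of scope.
* The additive-model engine handles one smooth plus one random intercept —
  exactly the structures needed here — and its edf/p-values are
  approximations of the kind mixed-GAM engines disagree on at the third
  decimal; conclusions should rest on the edf/significance/AIC decision
  pattern, which is what the tests assert.
* PTO is a relative index; comparing absolute values across populations
  with different flower totals is not meaningful.
* The simulator's unpollinated female flowers simply set no seed; pollen
  limitation of seed *quality* is not modelled.
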