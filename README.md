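# floralsync

Seasonal mating-opportunity analysis for monoecious, synchronously
protogynous clonal plants.

## The problem

In plants whose inflorescences pass through a female phase before any male
flower opens (synchronous protogyny), an inflorescence is functionally
unisexual on any given day. At the population scale this skews the daily
floral sex ratio — female-biased early in the season, male-biased late —
and so limits mate availability for plants flowering at the margins. The
*mating environment hypothesis* predicts that plants compensate by shifting
their sex allocation over the season (more male flowers in
early-flowering inflorescences), and that these shifts should translate
into siring success via male function. Testing this requires four linked
analyses that this package implements as a reusable, fully testable
pipeline for a clonal species:

1. **Clone assignment** — ramets → multilocus genotypes (MLGs) →
   multilocus lineages (MLLs = genets) from codominant SSR data, merging
   genotypes within one allelic difference (somatic variants, mistyping).
2. **Fractional paternity** — per-seed posterior siring probabilities π
   over candidate MLLs from an error-tolerant Mendelian likelihood
   `(1−ε)·T(seed | mother, candidate) + ε·P_HW(seed)`, with known mothers.
3. **Mating metrics** — the pollen-transfer-opportunity (PTO) index: per
   ramet *j* and day, `f_j = N_j^m / Σ_{l≠j} N_l^m` (share of the day's
   open male flowers) and `K_j = f_j · Σ_{i∉g(j)} N_i^f` (times female
   flowers open on other genets); per-genet daily `K_g = Σ_{j∈g} K_j`.
   Realized siring success `RS_g^m = Σ_seeds π` excluding selfed seeds.
4. **Seasonal models** — a binomial penalized-spline trend of the
   inflorescence sex ratio on first-flowering day, a Gaussian spline trend
   of daily genet PTO on day (each with an MLL random intercept and a
   linear mixed counterpart for AIC comparison), and a linear mixed model
   of `log10 RS` on date and PTO with stepwise selection.

A synthetic-population simulator with known clonal structure, phenology,
genotypes and true paternity drives every stage, so the whole chain is
verifiable against ground truth without any data download.

## Worked example

```python
from floralsync import (
    PopulationConfig, simulate_dataset, assign_clones, assign_paternity,
    DailyFloralMatrix, pto_genet, siring_success, sex_ratio_table,
    SexRatioTrendModel, PTOTrendModel, SiringSuccessModel)

ds = simulate_dataset(PopulationConfig(rng_seed=1))       # 169 genets
clones = assign_clones(ds.ramet_genotypes)
print(clones.n_mlgs, clones.n_mlls)                       # 343 180

pat = assign_paternity(ds.seeds, ds.ramet_genotypes, clones,
                       restrict_by_phenology=ds.phenology)
matrix = DailyFloralMatrix.from_phenology(
    ds.phenology, clones.mll_of_ramet())
pto_daily, _ = pto_genet(matrix)
siring, _ = siring_success(pat)

fit = SiringSuccessModel(siring, pto_daily).fit()
print(fit.summary())
```

which prints (abridged):

```
Linear mixed models of log10 siring success (n = 382 genet-days, 112 sire genets, selfed seeds excluded)
model [date]  AIC 55.10  F = 2.33 (1, 269.0), p = 0.128
model [pto]  AIC -3.81  F = 66.1 (1, 269.0), p = 1.6e-14 *selected*
    intercept  -0.09457 +/- 0.0209  t = -4.53  p = 8.84e-06
    K_day       0.02203 +/- 0.00271  t =  8.13  p = 1.6e-14
model [date+pto]  AIC -2.29  F = 33.2 (2, 268.0), p = 1.28e-13
```

Under the simulator's default spatially uniform mating (siring exactly
proportional to male-flower share), pollen-transfer opportunity strongly
predicts siring success and the PTO-only model wins the AIC comparison.
Re-running with `kernel_scale=0.5` — strong near-neighbour pollen
dispersal — halves the PTO coefficient and, across replicates, drops the
detection rate (1.0 → 0.7 over the 10 seeds the acceptance script runs):
spatial restriction alone can erase the PTO–siring link even though the
seasonal PTO trend itself is unchanged.

The trend models work the same way:

```python
sr = sex_ratio_table(ds.inflorescences, mll_of_ramet=clones.mll_of_ramet())
print(SexRatioTrendModel(sr).fit().summary())
print(PTOTrendModel(pto_daily).fit().summary())
```

reporting the smooth term's effective degrees of freedom, its approximate
test and p-value, both AICs (spline vs linear mixed counterpart), and the
MLL random-intercept variance.

## Command line

```bash
floralsync run-all --config cfg.yaml --seed 7
floralsync simulate --config cfg.yaml       # or any single stage:
floralsync assign-clones ... paternity ... pto ... siring ... trends
floralsync validate --config cfg.yaml
```

All tables are plain CSV with documented headers (see `floralsync.io`);
every stage writes a provenance JSON (seed, config hash, input checksums)
and is byte-identical under a fixed seed.

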