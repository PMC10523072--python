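"""Synthetic monoecious, synchronously protogynous populations.

Generates clonal populations with known genet structure, spatial layout,
flowering phenology, codominant microsatellite genotypes and true seed
paternity, so that every downstream analysis stage (clone clustering,
fractional paternity, pollen-transfer opportunity, seasonal models) can be
tested against ground truth.

Biology emulated
----------------
* Clonal growth: each genet comprises 1..``max_ramets`` ramets; ramets of a
  genet are spatially clustered around a genet centre (stolon growth).
* Synchronous protogyny: each inflorescence opens all of its female flowers
  over a short initial window, then its male flowers over a staggered span;
  every flower is open for exactly one day, so an inflorescence is
  functionally unisexual on any given day and within-ramet selfing is
  structurally impossible.
* Mating: pollen moves to an open female flower from ramets with open male
  flowers the same day, with donor weight proportional to the donor's open
  male-flower count times a negative-exponential function of distance
  (``kernel_scale=None`` means spatially uniform mating).  Pollen transfer
  between ramets of the same genet produces geitonogamous selfed seeds.
* Genotypes: seven codominant loci by default, Hardy-Weinberg draws from
  Dirichlet-distributed allele frequencies; somatic variants perturb one
  allele of a ramet's genotype; per-allele mistyping noise is applied to the
  observed tables.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PopulationConfig",
    "SyntheticDataset",
    "generate_population",
    "generate_phenology",
    "generate_genotypes",
    "simulate_mating",
    "simulate_dataset",
]


class ConfigurationError(ValueError):
    """Invalid simulator configuration."""


@dataclass(frozen=True)
class PopulationConfig:
    """Parameters of the synthetic population.

    Defaults describe a ~25 x 60 m stand of about 169 genets / 940 flowering
    ramets flowering over Julian days 199-240, with ~40% singleton genets and
    a maximum genet size of 35 ramets.

    Parameters
    ----------
    n_genets : int
        Number of genets (multilocus lineages) in the stand.
    singleton_prob : float
        Probability a genet consists of a single ramet.
    genet_size_nb_size, genet_size_nb_mean : float
        Non-singleton genets have ``2 + NegBin(size, mean)`` ramets,
        truncated at ``max_ramets``.
    max_ramets : int
        Hard cap on ramets per genet.
    arena : (float, float)
        Rectangular extent in metres; origin at one corner.
    genet_scatter_sd : float
        Gaussian scatter (m) of ramets around their genet centre.
    season : (int, int)
        First and last Julian day of the flowering season.
    start_beta : (float, float)
        Beta shape parameters of the first-flowering-day law, scaled onto
        the season (few inflorescences open early, most near the late-season
        mode).
    flowers_mean, flowers_sigma : float
        Poisson-lognormal law for total flowers per inflorescence:
        ``Poisson(exp(Normal(log(mean) - sigma^2/2, sigma)))``, floored at 2.
    sex_logit : tuple of float
        Polynomial coefficients (constant, linear[, quadratic]) of the
        expected logit male share as a function of the inflorescence's
        first-flowering day scaled to [-1, 1] over the season.  The default
        makes early inflorescences male-biased and late ones female-biased.
    female_phase_days : int
        Days over which the female flowers of an inflorescence open
        (near-simultaneous; 1-2).
    male_stagger_days : int
        Span of days over which male flowers open, after female phase ends.
    n_loci, alleles_per_locus : int
        Microsatellite panel dimensions.
    allele_freq_concentration : float
        Symmetric Dirichlet concentration of the per-locus allele
        frequencies.
    somatic_mlg_rate : float
        Probability a ramet's true genotype differs from its genet genotype
        by exactly one allele at one locus (somatic variant).
    genotyping_error : float
        Per-allele mistyping probability applied to the *observed* ramet and
        seed genotype tables.
    missing_rate : float
        Per-locus probability that an observed genotype is missing (scored
        0/0).
    kernel_scale : float or None
        Negative-exponential pollen-dispersal scale in metres; ``None`` (or
        ``inf``) gives spatially uniform mating.
    seed_sample_fraction : float
        Fraction of pollinated female flowers whose seed is genotyped.
    rng_seed : int
        Seed for all randomness.
    """

    n_genets: int = 169
    singleton_prob: float = 0.40
    genet_size_nb_size: float = 0.7
    genet_size_nb_mean: float = 6.63
    max_ramets: int = 35
    arena: tuple[float, float] = (25.0, 60.0)
    genet_scatter_sd: float = 2.0
    season: tuple[int, int] = (199, 240)
    start_beta: tuple[float, float] = (5.0, 2.0)
    flowers_mean: float = 10.0
    flowers_sigma: float = 0.45
    sex_logit: tuple[float, ...] = (0.45, -1.4)
    female_phase_days: int = 2
    male_stagger_days: int = 4
    n_loci: int = 7
    alleles_per_locus: int = 15
    allele_freq_concentration: float = 1.0
    somatic_mlg_rate: float = 0.05
    genotyping_error: float = 0.01
    missing_rate: float = 0.0
    kernel_scale: float | None = None
    seed_sample_fraction: float = 0.095
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genets < 1:
            raise ConfigurationError("n_genets must be >= 1")
        if not (self.season[0] < self.season[1]):
            raise ConfigurationError("season first_day must precede last_day")
        for name in ("singleton_prob", "somatic_mlg_rate", "genotyping_error",
                     "missing_rate", "seed_sample_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.max_ramets < 1:
            raise ConfigurationError("max_ramets must be >= 1")
        if self.female_phase_days < 1 or self.male_stagger_days < 1:
            raise ConfigurationError("phase spans must be >= 1 day")
        if self.n_loci < 1 or self.alleles_per_locus < 2:
            raise ConfigurationError("need >= 1 locus with >= 2 alleles")
        if self.genet_size_nb_mean <= 0 or self.genet_size_nb_size <= 0:
            raise ConfigurationError("negative-binomial parameters must be > 0")
        if self.kernel_scale is not None and self.kernel_scale <= 0:
            raise ConfigurationError("kernel_scale must be > 0 (or None)")

    def replace(self, **kw) -> "PopulationConfig":
        return replace(self, **kw)


@dataclass
class SyntheticDataset:
    """All tables produced by one simulator run.

    ``ramets``: ramet_id, genet_id, x_m, y_m.
    ``inflorescences``: inflorescence_id, ramet_id, genet_id,
    first_flowering_day, n_female, n_male.
    ``phenology``: day, ramet_id, inflorescence_id, n_open_female,
    n_open_male (one row per ramet-day with any open flower).
    ``ramet_genotypes`` / ``seeds``: wide tables with ``L{i}_a1``/``L{i}_a2``
    integer allele columns, 0 = missing.
    ``truth``: seed_id, true_sire_ramet, true_sire_genet, pollination_day,
    is_selfed.
    ``allele_freqs``: locus, allele, freq (the generating frequencies).
    ``unpollinated``: per-day counts of female flowers left without any
    available pollen donor.
    """

    config: PopulationConfig
    ramets: pd.DataFrame
    inflorescences: pd.DataFrame
    phenology: pd.DataFrame
    ramet_genotypes: pd.DataFrame
    true_genotypes: pd.DataFrame
    allele_freqs: pd.DataFrame
    seeds: pd.DataFrame = field(default_factory=pd.DataFrame)
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    unpollinated: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write(self, outdir) -> dict:
        """Write the pipeline's CSV inputs into *outdir*; return paths."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("coordinates", self.ramets),
            ("inflorescences", self.inflorescences),
            ("phenology", self.phenology),
            ("ramet_genotypes", self.ramet_genotypes),
            ("seeds", self.seeds),
            ("truth", self.truth),
            ("allele_freqs", self.allele_freqs),
        ]:
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        return paths


# ---------------------------------------------------------------------------
# stage 1: population structure

def _genet_sizes(cfg: PopulationConfig, rng: np.random.Generator) -> np.ndarray:
    sizes = np.ones(cfg.n_genets, dtype=int)
    big = rng.random(cfg.n_genets) >= cfg.singleton_prob
    n_big = int(big.sum())
    if n_big:
        r = cfg.genet_size_nb_size
        p = r / (r + cfg.genet_size_nb_mean)
        draw = 2 + rng.negative_binomial(r, p, size=n_big)
        sizes[big] = np.minimum(draw, cfg.max_ramets)
    return sizes


def generate_population(config: PopulationConfig) -> pd.DataFrame:
    """Generate genets, their ramets and ramet coordinates.

    Returns the ``ramets`` table (ramet_id, genet_id, x_m, y_m).  Ramets of
    one genet are scattered around a uniform-random genet centre, so clones
    form spatial patches while singletons can be isolated.
    """
    rng = np.random.default_rng(config.rng_seed)
    sizes = _genet_sizes(config, rng)
    w, h = config.arena
    centres = rng.uniform([0, 0], [w, h], size=(config.n_genets, 2))
    rows = []
    r_idx = 0
    for g_idx, (size, centre) in enumerate(zip(sizes, centres)):
        gid = f"G{g_idx + 1:03d}"
        offs = rng.normal(0.0, config.genet_scatter_sd, size=(size, 2))
        xy = np.clip(centre + offs, [0, 0], [w, h])
        for k in range(size):
            rows.append((f"R{r_idx + 1:04d}", gid, xy[k, 0], xy[k, 1]))
            r_idx += 1
    return pd.DataFrame(rows, columns=["ramet_id", "genet_id", "x_m", "y_m"])


# ---------------------------------------------------------------------------
# stage 2: phenology

def _spread_counts(total: int, n_days: int, rng: np.random.Generator) -> np.ndarray:
    """Assign *total* single-day flowers to *n_days* consecutive days.

    Every day window is available; flowers fall in days via a flat
    multinomial, so totals are conserved exactly.
    """
    if n_days == 1:
        return np.array([total])
    return rng.multinomial(total, np.full(n_days, 1.0 / n_days))


def generate_phenology(
    population: pd.DataFrame, config: PopulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate daily open-flower records and inflorescence summaries.

    One inflorescence per flowering ramet.  Female flowers open over the
    first ``female_phase_days`` days from the first flowering day; male
    flowers open over the following ``male_stagger_days`` days, so every
    female-phase day strictly precedes every male-phase day (synchronous
    protogyny) and each flower is open exactly one day.
    """
    rng = np.random.default_rng(_stage_seed(config.rng_seed, "phenology"))
    first_day, last_day = config.season
    df_, dm_ = config.female_phase_days, config.male_stagger_days
    span = (last_day - df_ - dm_ + 1) - first_day
    if span < 1:
        raise ConfigurationError("season too short for the flowering phases")

    n = len(population)
    a, b = config.start_beta
    starts = first_day + np.floor(rng.beta(a, b, size=n) * (span + 1)).astype(int)
    starts = np.minimum(starts, first_day + span)

    mu_log = math.log(config.flowers_mean) - config.flowers_sigma**2 / 2.0
    lam = np.exp(rng.normal(mu_log, config.flowers_sigma, size=n))
    totals = np.maximum(rng.poisson(lam), 2)

    z = (starts - (first_day + last_day) / 2.0) / ((last_day - first_day) / 2.0)
    logit = np.zeros(n)
    for k, c in enumerate(config.sex_logit):
        logit += c * z**k
    p_male = 1.0 / (1.0 + np.exp(-logit))
    n_male = rng.binomial(totals, p_male)
    n_female = totals - n_male

    phen_rows: list[tuple] = []
    infl_rows: list[tuple] = []
    for i in range(n):
        rid = population["ramet_id"].iat[i]
        gid = population["genet_id"].iat[i]
        iid = f"I{i + 1:04d}"
        t0 = int(starts[i])
        infl_rows.append((iid, rid, gid, t0, int(n_female[i]), int(n_male[i])))
        fem = _spread_counts(int(n_female[i]), df_, rng)
        mal = _spread_counts(int(n_male[i]), dm_, rng)
        daily: dict[int, list[int]] = {}
        for d, c in enumerate(fem):
            if c:
                daily.setdefault(t0 + d, [0, 0])[0] += int(c)
        for d, c in enumerate(mal):
            if c:
                daily.setdefault(t0 + df_ + d, [0, 0])[1] += int(c)
        for day in sorted(daily):
            f, m = daily[day]
            phen_rows.append((day, rid, iid, f, m))

    phenology = pd.DataFrame(
        phen_rows,
        columns=["day", "ramet_id", "inflorescence_id", "n_open_female", "n_open_male"],
    )
    inflorescences = pd.DataFrame(
        infl_rows,
        columns=["inflorescence_id", "ramet_id", "genet_id",
                 "first_flowering_day", "n_female", "n_male"],
    )
    return phenology, inflorescences


# ---------------------------------------------------------------------------
# stage 3: genotypes

def _stage_seed(base: int, stage: str) -> int:
    # independent, reproducible streams per stage; stays below 2**31
    # (zlib.crc32 is stable across processes, unlike hash())
    return (int(base) * 1000003 + zlib.crc32(stage.encode())) & 0x7FFFFFFF


def _allele_label(a: int) -> int:
    return 100 + 2 * a


def genotype_columns(n_loci: int) -> list[str]:
    return [f"L{i + 1}_a{j}" for i in range(n_loci) for j in (1, 2)]


def _geno_to_frame(ids: np.ndarray, id_col: str, geno: np.ndarray) -> pd.DataFrame:
    n, n_loci, _ = geno.shape
    flat = geno.reshape(n, n_loci * 2)
    out = pd.DataFrame(flat, columns=genotype_columns(n_loci))
    out.insert(0, id_col, ids)
    return out


def generate_genotypes(
    population: pd.DataFrame, config: PopulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate observed and true ramet genotypes plus allele frequencies.

    Returns ``(observed, true, allele_freqs)``.  All ramets of a genet share
    the genet's multilocus genotype, except ramets hit by
    ``somatic_mlg_rate``, whose *true* genotype differs by exactly one allele
    at one locus.  The observed table further applies per-allele mistyping
    (replacement by a random frequency-weighted allele) and per-locus
    missingness.
    """
    rng = np.random.default_rng(_stage_seed(config.rng_seed, "genotypes"))
    L, A = config.n_loci, config.alleles_per_locus
    freqs = rng.dirichlet(np.full(A, config.allele_freq_concentration), size=L)

    genets = population["genet_id"].unique()
    g_index = {g: i for i, g in enumerate(genets)}
    genet_geno = np.empty((len(genets), L, 2), dtype=int)
    for l in range(L):
        draws = rng.choice(A, size=(len(genets), 2), p=freqs[l])
        genet_geno[:, l, :] = np.sort(draws, axis=1)

    n = len(population)
    true_geno = genet_geno[[g_index[g] for g in population["genet_id"]]].copy()
    hit = rng.random(n) < config.somatic_mlg_rate
    # the founder (first) ramet of a genet always carries the genet MLG, so
    # every somatic variant stays within one allelic step of an observed
    # reference genotype
    founders = ~population["genet_id"].duplicated().to_numpy()
    hit &= ~founders
    for i in np.flatnonzero(hit):
        l = rng.integers(L)
        slot = rng.integers(2)
        old = true_geno[i, l, slot]
        new = rng.integers(A - 1)
        if new >= old:
            new += 1
        true_geno[i, l, slot] = new
        true_geno[i, l] = np.sort(true_geno[i, l])

    obs = _apply_observation_noise(true_geno, freqs, config, rng)

    labelled_true = np.vectorize(_allele_label)(true_geno)
    labelled_obs = np.where(obs >= 0, 100 + 2 * obs, 0)
    ids = population["ramet_id"].to_numpy()
    observed = _geno_to_frame(ids, "ramet_id", labelled_obs)
    true_df = _geno_to_frame(ids, "ramet_id", labelled_true)
    af = pd.DataFrame(
        [(f"L{l + 1}", _allele_label(a), freqs[l, a])
         for l in range(L) for a in range(A)],
        columns=["locus", "allele", "freq"],
    )
    return observed, true_df, af


def _apply_observation_noise(
    geno: np.ndarray, freqs: np.ndarray, config: PopulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-allele mistyping plus per-locus missingness; -1 marks missing."""
    out = geno.copy()
    n, L, _ = out.shape
    if config.genotyping_error > 0:
        err = rng.random(out.shape) < config.genotyping_error
        for l in range(L):
            k = int(err[:, l, :].sum())
            if k:
                out[:, l, :][err[:, l, :]] = rng.choice(
                    freqs.shape[1], size=k, p=freqs[l]
                )
        out = np.sort(out, axis=2)
    if config.missing_rate > 0:
        miss = rng.random((n, L)) < config.missing_rate
        out[miss] = -1
    return out


# ---------------------------------------------------------------------------
# stage 4: mating

def simulate_mating(
    phenology: pd.DataFrame,
    true_genotypes: pd.DataFrame,
    ramets: pd.DataFrame,
    config: PopulationConfig,
    allele_freqs: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate pollination and seed set; return (seeds, truth, unpollinated).

    For each sampled open female flower on day *k* the sire ramet is drawn
    among ramets with open male flowers on day *k* with probability
    proportional to ``N_male * exp(-distance / kernel_scale)``
    (distance-free when ``kernel_scale`` is None).  The seed genotype takes
    one maternal and one paternal allele per locus (Mendelian segregation
    from the *true* parental genotypes), then observation noise is applied.
    Days on which female flowers are open but no ramet anywhere has an open
    male flower yield no seeds and are logged in the third return value.
    """
    rng = np.random.default_rng(_stage_seed(config.rng_seed, "mating"))
    L = config.n_loci
    gcols = genotype_columns(L)
    geno = {
        rid: row.reshape(L, 2)
        for rid, row in zip(
            true_genotypes["ramet_id"],
            true_genotypes[gcols].to_numpy(dtype=int),
        )
    }
    coord = ramets.set_index("ramet_id")[["x_m", "y_m"]]
    genet_of = ramets.set_index("ramet_id")["genet_id"].to_dict()

    if allele_freqs is not None:
        err_alleles = {
            loc: (sub["allele"].to_numpy(), sub["freq"].to_numpy())
            for loc, sub in allele_freqs.groupby("locus")
        }
    else:
        err_alleles = None

    seed_rows, truth_rows, unpoll = [], [], []
    sid = 0
    for day, day_tab in phenology.groupby("day", sort=True):
        donors = day_tab[day_tab["n_open_male"] > 0]
        mothers = day_tab[day_tab["n_open_female"] > 0]
        if mothers.empty:
            continue
        if donors.empty:
            unpoll.append((int(day), int(mothers["n_open_female"].sum())))
            continue
        d_ids = donors["ramet_id"].to_numpy()
        d_xy = coord.loc[d_ids].to_numpy()
        d_w_base = donors["n_open_male"].to_numpy(dtype=float)
        for _, mrow in mothers.iterrows():
            mother = mrow["ramet_id"]
            n_f = int(mrow["n_open_female"])
            n_sample = int(rng.binomial(n_f, config.seed_sample_fraction))
            if n_sample == 0:
                continue
            w = d_w_base.copy()
            # the mother ramet is in female phase, so it never appears among
            # donors; same-genet *other* ramets can (geitonogamy)
            if config.kernel_scale is not None and np.isfinite(config.kernel_scale):
                mx, my = coord.loc[mother]
                dist = np.hypot(d_xy[:, 0] - mx, d_xy[:, 1] - my)
                w = w * np.exp(-dist / config.kernel_scale)
            if w.sum() <= 0:
                unpoll.append((int(day), n_sample))
                continue
            w = w / w.sum()
            sires = rng.choice(len(d_ids), size=n_sample, p=w)
            for s in sires:
                sire = d_ids[s]
                sid += 1
                seed_id = f"S{sid:04d}"
                child = _mendelian_cross(geno[mother], geno[sire], rng)
                seed_rows.append(
                    (seed_id, mother, int(day), child))
                truth_rows.append((
                    seed_id, sire, genet_of[sire], int(day),
                    genet_of[sire] == genet_of[mother],
                ))

    if seed_rows:
        child_geno = np.stack([r[3] for r in seed_rows])
        child_geno = _apply_observation_noise(
            _labels_to_indices(child_geno), _freq_matrix(allele_freqs, config),
            config, rng,
        ) if err_alleles is not None else _labels_to_indices(child_geno)
        labelled = np.where(child_geno >= 0, 100 + 2 * child_geno, 0)
        seeds = _geno_to_frame(
            np.array([r[0] for r in seed_rows]), "seed_id", labelled)
        seeds.insert(1, "mother_ramet_id", [r[1] for r in seed_rows])
        seeds.insert(2, "pollination_day", [r[2] for r in seed_rows])
    else:
        seeds = pd.DataFrame(
            columns=["seed_id", "mother_ramet_id", "pollination_day"]
            + genotype_columns(L))
    truth = pd.DataFrame(
        truth_rows,
        columns=["seed_id", "true_sire_ramet", "true_sire_genet",
                 "pollination_day", "is_selfed"],
    )
    unpollinated = pd.DataFrame(unpoll, columns=["day", "n_unpollinated"])
    return seeds, truth, unpollinated


def _labels_to_indices(labelled: np.ndarray) -> np.ndarray:
    return np.where(labelled > 0, (labelled - 100) // 2, -1)


def _freq_matrix(allele_freqs: pd.DataFrame, config: PopulationConfig) -> np.ndarray:
    mat = np.zeros((config.n_loci, config.alleles_per_locus))
    for _, row in allele_freqs.iterrows():
        l = int(str(row["locus"])[1:]) - 1
        a = (int(row["allele"]) - 100) // 2
        mat[l, a] = row["freq"]
    return mat


def _mendelian_cross(
    mom: np.ndarray, dad: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    L = mom.shape[0]
    mi = rng.integers(2, size=L)
    di = rng.integers(2, size=L)
    child = np.stack([mom[np.arange(L), mi], dad[np.arange(L), di]], axis=1)
    return np.sort(child, axis=1)


# ---------------------------------------------------------------------------

def simulate_dataset(config: PopulationConfig | None = None, **overrides) -> SyntheticDataset:
    """Run the whole simulator and return every table as a SyntheticDataset."""
    if config is None:
        config = PopulationConfig(**overrides)
    elif overrides:
        config = config.replace(**overrides)
    ramets = generate_population(config)
    phenology, inflorescences = generate_phenology(ramets, config)
    observed, true_df, af = generate_genotypes(ramets, config)
    seeds, truth, unpoll = simulate_mating(phenology, true_df, ramets, config, af)
    return SyntheticDataset(
        config=config,
        ramets=ramets,
        inflorescences=inflorescences,
        phenology=phenology,
        ramet_genotypes=observed,
        true_genotypes=true_df,
        allele_freqs=af,
        seeds=seeds,
        truth=truth,
        unpollinated=unpoll,
    )
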