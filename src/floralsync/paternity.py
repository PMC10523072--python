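"""Fractional paternity from codominant genotypes with known mothers.

Each genotyped seed has a known maternal ramet; candidate sires are the
population's distinct multilocus genotypes (MLGs).  The per-locus likelihood
of a candidate is an error-tolerant Mendelian transition probability

    (1 - eps) * T(offspring | mother, candidate) + eps * P_HW(offspring)

where ``T`` averages over the four equally likely gamete pairs and ``P_HW``
is the Hardy-Weinberg probability of the offspring genotype (the mistyping
mixture of Marshall et al.'s CERVUS likelihood).  A locus missing in any
party is uninformative (likelihood 1).  Per-seed posteriors over candidates
(``pi``) multiply locus likelihoods with a prior, are normalized to 1, and
MLG-level mass is summed into MLL-level mass.  An optional UNSAMPLED father
class integrates the paternal gamete over population allele frequencies.

Maternal-incompatible loci are *not* hard zeros: the error mixture leaves
``eps * P_HW`` mass, so a single mistyped maternal allele cannot veto every
candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from floralsync.clones import MISSING, genotypes_to_array

__all__ = [
    "PaternityConfig",
    "transmission_prob",
    "hardy_weinberg_prob",
    "locus_likelihood",
    "fractional_paternity",
    "assign_paternity",
    "classify_selfed",
    "estimate_allele_freqs",
    "UNSAMPLED",
]

UNSAMPLED = "UNSAMPLED"


@dataclass(frozen=True)
class PaternityConfig:
    """Settings for fractional paternity.

    error_rate: per-locus mistyping probability eps in the likelihood
    mixture.  include_unsampled / unsampled_prior: whether to reserve prior
    mass for a father outside the candidate set (default off: the motivating
    population is isolated and the simulator is closed).
    """

    error_rate: float = 0.01
    include_unsampled: bool = False
    unsampled_prior: float = 0.0
    min_pi: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate <= 1.0):
            raise ValueError("error_rate must be in [0, 1]")
        if not (0.0 <= self.unsampled_prior < 1.0):
            raise ValueError("unsampled_prior must be in [0, 1)")
        if not (0.0 <= self.min_pi < 1.0):
            raise ValueError("min_pi must be in [0, 1)")


def transmission_prob(offspring, mother, father) -> float:
    """Mendelian probability of the offspring single-locus genotype.

    Each argument is an unordered allele pair.  Averages over the four
    equally likely gamete combinations; 0 if the pair cannot produce the
    offspring genotype.
    """
    off = tuple(sorted(offspring))
    hits = sum(
        tuple(sorted((m, f))) == off for m in mother for f in father
    )
    return hits / 4.0


def hardy_weinberg_prob(offspring, freqs: dict) -> float:
    """Hardy-Weinberg probability of a single-locus genotype.

    ``freqs`` maps allele label -> frequency.  Unseen alleles get frequency
    0 (their HW probability is 0 rather than an error).
    """
    a, b = offspring
    pa = freqs.get(a, 0.0)
    pb = freqs.get(b, 0.0)
    return pa * pb * (1.0 if a == b else 2.0)


def _maternal_transmission(offspring, mother, freqs: dict) -> float:
    """P(offspring | mother, random HW father) for the UNSAMPLED class."""
    off = tuple(sorted(offspring))
    p = 0.0
    for m in mother:  # each maternal gamete has probability 1/2
        for pat, fr in freqs.items():
            if tuple(sorted((m, pat))) == off:
                p += 0.5 * fr
    return p


def locus_likelihood(offspring, mother, candidate, freqs: dict, eps: float) -> float:
    """Error-tolerant per-locus likelihood of a candidate father.

    Missing genotype in any party (offspring, mother or candidate) makes
    the locus uninformative (returns 1).  ``candidate=None`` requests the
    UNSAMPLED-father likelihood (paternal gamete integrated over ``freqs``).
    """
    if _is_missing(offspring) or _is_missing(mother):
        return 1.0
    if candidate is None:
        t = _maternal_transmission(offspring, mother, freqs)
    else:
        if _is_missing(candidate):
            return 1.0
        t = transmission_prob(offspring, mother, candidate)
    return (1.0 - eps) * t + eps * hardy_weinberg_prob(offspring, freqs)


def _is_missing(pair) -> bool:
    return pair is None or pair[0] == MISSING or pair[1] == MISSING


def estimate_allele_freqs(
    genotypes: pd.DataFrame, id_col: str = "ramet_id",
    dedupe: pd.Series | None = None,
) -> list[dict]:
    """Per-locus allele frequencies from a wide genotype table.

    Returns one {allele: freq} dict per locus.  ``dedupe`` may map ids to
    clone labels, in which case one representative per clone is counted so
    large genets do not dominate the frequency estimate.
    """
    tab = genotypes
    if dedupe is not None:
        keep = ~pd.Series(
            [dedupe.get(i) for i in genotypes[id_col]], index=genotypes.index
        ).duplicated()
        tab = genotypes[keep]
    _, arr = genotypes_to_array(tab, id_col)
    out = []
    for l in range(arr.shape[1]):
        alleles = arr[:, l, :].ravel()
        alleles = alleles[alleles != MISSING]
        if len(alleles) == 0:
            out.append({})
            continue
        vals, counts = np.unique(alleles, return_counts=True)
        tot = counts.sum()
        out.append({int(v): c / tot for v, c in zip(vals, counts)})
    return out


def fractional_paternity(
    seed_geno: np.ndarray,
    mother_geno: np.ndarray,
    candidates: dict[str, np.ndarray],
    allele_freqs: list[dict],
    config: PaternityConfig = PaternityConfig(),
    priors: dict[str, float] | None = None,
) -> dict[str, float]:
    """Posterior paternity probabilities pi for one seed.

    ``candidates`` maps candidate id (e.g. MLG id) to an (n_loci, 2) allele
    array.  Returns {candidate_id: pi} normalized to 1, including an
    ``UNSAMPLED`` key when enabled.  If every candidate has zero likelihood
    and no UNSAMPLED class is enabled, returns an empty dict (the seed is
    unassigned, not an error).
    """
    eps = config.error_rate
    names = list(candidates)
    if priors is None:
        base = 1.0 - (config.unsampled_prior if config.include_unsampled else 0.0)
        priors = {n: base / max(len(names), 1) for n in names}
    liks = {}
    for name in names:
        cand = candidates[name]
        lik = priors.get(name, 0.0)
        for l in range(len(seed_geno)):
            lik *= locus_likelihood(
                seed_geno[l], mother_geno[l], cand[l], allele_freqs[l], eps)
            if lik == 0.0:
                break
        liks[name] = lik
    if config.include_unsampled:
        lik = config.unsampled_prior
        for l in range(len(seed_geno)):
            lik *= locus_likelihood(
                seed_geno[l], mother_geno[l], None, allele_freqs[l], eps)
        liks[UNSAMPLED] = lik
    total = sum(liks.values())
    if total <= 0.0:
        return {}
    pi = {n: v / total for n, v in liks.items() if v > 0.0}
    if config.min_pi > 0.0:
        # discard vanishing posterior mass (paternity software reports
        # candidates above a probability floor) and renormalize
        pi = {n: v for n, v in pi.items() if v >= config.min_pi}
        if not pi:
            return {}
        z = sum(pi.values())
        pi = {n: v / z for n, v in pi.items()}
    return pi


def classify_selfed(pi: dict[str, float], maternal_mll: str) -> float:
    """Selfing probability of a seed = pi mass on the maternal MLL."""
    return pi.get(maternal_mll, 0.0)


def assign_paternity(
    seeds: pd.DataFrame,
    ramet_genotypes: pd.DataFrame,
    clones,
    config: PaternityConfig = PaternityConfig(),
    allele_freqs: list[dict] | None = None,
    restrict_by_phenology: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fractional paternity for a whole seed table, aggregated to MLL level.

    Parameters
    ----------
    seeds : DataFrame
        seed_id, mother_ramet_id, pollination_day and locus columns.
    ramet_genotypes : DataFrame
        Observed ramet genotypes (candidate pool and mothers).
    clones : ClonalAssignment
        Ramet -> MLG -> MLL mapping; candidates are the distinct MLGs and
        posteriors are reported per MLL (MLG mass summed within MLL).
    allele_freqs : list of dict, optional
        Per-locus allele frequencies; estimated from one ramet per MLL when
        omitted.
    restrict_by_phenology : DataFrame, optional
        Phenology table (day, ramet_id, n_open_male): when given, the
        candidate set for each seed is limited to MLGs with at least one
        ramet bearing open male flowers on the seed's pollination day.

    Returns
    -------
    DataFrame with columns seed_id, mll_id, pi, selfed_flag,
    pollination_day.  Seeds with no compatible candidate (and no UNSAMPLED
    class) are absent; callers can diff seed ids to log them.
    """
    ids, arr = genotypes_to_array(ramet_genotypes)
    geno_of_ramet = dict(zip(ids, arr))
    mlg_of = dict(zip(clones.table["ramet_id"], clones.table["mlg_id"]))
    mll_of_mlg = dict(zip(clones.table["mlg_id"], clones.table["mll_id"]))
    mll_of_ramet = clones.mll_of_ramet()
    if allele_freqs is None:
        allele_freqs = estimate_allele_freqs(
            ramet_genotypes, dedupe=pd.Series(mll_of_ramet))

    all_candidates = clones.mlg_genotypes
    day_candidates: dict[int, dict[str, np.ndarray]] = {}
    if restrict_by_phenology is not None:
        ph = restrict_by_phenology
        for day, sub in ph[ph["n_open_male"] > 0].groupby("day"):
            mlgs = {mlg_of[r] for r in sub["ramet_id"] if r in mlg_of}
            day_candidates[int(day)] = {
                m: all_candidates[m] for m in sorted(mlgs)}

    seed_ids, seed_arr = genotypes_to_array(
        seeds.drop(columns=["mother_ramet_id", "pollination_day"]),
        id_col="seed_id")
    mothers = seeds["mother_ramet_id"].to_numpy()
    days = seeds["pollination_day"].to_numpy()

    rows = []
    for sidx in range(len(seed_ids)):
        mother = mothers[sidx]
        if mother not in geno_of_ramet:
            continue
        day = int(days[sidx])
        cands = day_candidates.get(day, all_candidates) \
            if restrict_by_phenology is not None else all_candidates
        if not cands:
            continue
        pi_mlg = fractional_paternity(
            seed_arr[sidx], geno_of_ramet[mother], cands, allele_freqs, config)
        if not pi_mlg:
            continue
        pi_mll: dict[str, float] = {}
        for mlg, p in pi_mlg.items():
            key = UNSAMPLED if mlg == UNSAMPLED else mll_of_mlg[mlg]
            pi_mll[key] = pi_mll.get(key, 0.0) + p
        maternal_mll = mll_of_ramet.get(mother)
        for mll, p in sorted(pi_mll.items()):
            rows.append((
                seed_ids[sidx], mll, p, mll == maternal_mll, day))
    return pd.DataFrame(
        rows, columns=["seed_id", "mll_id", "pi", "selfed_flag",
                       "pollination_day"])
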