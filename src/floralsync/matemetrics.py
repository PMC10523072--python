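"""Mating-opportunity and siring-success statistics.

Implements, on daily open-flower matrices:

* the inflorescence sex ratio (proportion of male flowers),
* the daily male-flower fraction per ramet
  ``f_j = N_j^m / sum_{l != j} N_l^m``,
* the pollen-transfer-opportunity index per ramet-day
  ``K_ij = f_j * sum_{i not in g(j)} N_i^f`` (female flowers on *other
  genets* only — geitonogamous opportunities are excluded),
* the per-genet PTO ``K_g`` (daily sum over the genet's ramets, season
  total over days),
* realized siring success per MLL (per day and season total)
  ``RS_i^m = sum_j pi_ijk`` over outcrossed seed mass.

The PTO index is relative and unbounded above.  When one ramet holds every
open male flower of a day, the fraction's denominator is 0; the sole donor
is then given ``f = 1`` (the monopoly limit: its opportunity is all open
female flowers on other genets), flagged in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DailyFloralMatrix",
    "inflorescence_sex_ratio",
    "sex_ratio_table",
    "male_fraction",
    "pto_ramet_day",
    "pto_genet",
    "siring_success",
]


@dataclass
class DailyFloralMatrix:
    """Open-flower counts as dense (ramet x day) matrices.

    ``female``/``male`` are nonnegative integer arrays aligned on
    ``ramet_ids`` (rows) and ``days`` (columns); ``genet_of`` maps every
    ramet id to its genet (MLL) id.
    """

    ramet_ids: np.ndarray
    days: np.ndarray
    female: np.ndarray
    male: np.ndarray
    genet_of: dict[str, str]

    @classmethod
    def from_phenology(
        cls, phenology: pd.DataFrame, genet_of: dict[str, str]
    ) -> "DailyFloralMatrix":
        """Build matrices from a long phenology table.

        Expects columns day, ramet_id, n_open_female, n_open_male; multiple
        inflorescences of one ramet on one day are summed.
        """
        agg = (
            phenology.groupby(["ramet_id", "day"])[["n_open_female", "n_open_male"]]
            .sum()
            .reset_index()
        )
        if (agg[["n_open_female", "n_open_male"]] < 0).any().any():
            raise ValueError("negative open-flower counts")
        fem = agg.pivot(index="ramet_id", columns="day", values="n_open_female")
        mal = agg.pivot(index="ramet_id", columns="day", values="n_open_male")
        fem = fem.fillna(0.0)
        mal = mal.fillna(0.0)
        missing = [r for r in fem.index if r not in genet_of]
        if missing:
            raise ValueError(f"ramets without genet assignment: {missing[:5]}")
        return cls(
            ramet_ids=fem.index.to_numpy(),
            days=fem.columns.to_numpy(dtype=int),
            female=fem.to_numpy(dtype=float),
            male=mal.to_numpy(dtype=float),
            genet_of=dict(genet_of),
        )

    @property
    def genet_ids(self) -> np.ndarray:
        return np.array(sorted({self.genet_of[r] for r in self.ramet_ids}))

    def genet_indicator(self) -> tuple[np.ndarray, np.ndarray]:
        """(genet ids, G x R 0/1 membership matrix)."""
        gids = self.genet_ids
        gpos = {g: i for i, g in enumerate(gids)}
        ind = np.zeros((len(gids), len(self.ramet_ids)))
        for j, r in enumerate(self.ramet_ids):
            ind[gpos[self.genet_of[r]], j] = 1.0
        return gids, ind


def inflorescence_sex_ratio(n_male: int, n_total: int) -> float:
    """Proportion of male flowers in an inflorescence."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not (0 <= n_male <= n_total):
        raise ValueError("need 0 <= n_male <= n_total")
    return n_male / n_total


def sex_ratio_table(
    inflorescences: pd.DataFrame, mll_of_ramet: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-inflorescence sex-ratio records for the seasonal trend model.

    Input columns: inflorescence_id, ramet_id, first_flowering_day,
    n_female, n_male (a genet_id column is used if present, else
    ``mll_of_ramet`` must supply the clone of each ramet).  Inflorescences
    with zero flowers are dropped.
    """
    tab = inflorescences.copy()
    tab["n_total"] = tab["n_female"] + tab["n_male"]
    tab = tab[tab["n_total"] >= 1].copy()
    if mll_of_ramet is not None:
        tab["mll_id"] = [mll_of_ramet[r] for r in tab["ramet_id"]]
    elif "genet_id" in tab.columns:
        tab["mll_id"] = tab["genet_id"]
    else:
        raise ValueError("need genet_id column or mll_of_ramet mapping")
    tab["sex_ratio"] = tab["n_male"] / tab["n_total"]
    return tab[["inflorescence_id", "ramet_id", "mll_id",
                "first_flowering_day", "n_male", "n_total", "sex_ratio"]]


def male_fraction(matrix: DailyFloralMatrix) -> pd.DataFrame:
    """Daily fraction of open male flowers per ramet.

    Returns a long table (ramet_id, day, f_male, sole_donor).  f is 0 for
    ramets without open male flowers; when a ramet holds every open male
    flower of the day, f = 1 and sole_donor is True.
    """
    f, sole = _male_fraction_arrays(matrix)
    return _long(matrix, {"f_male": f, "sole_donor": sole})


def _male_fraction_arrays(matrix: DailyFloralMatrix):
    m = matrix.male
    tot = m.sum(axis=0, keepdims=True)
    other = tot - m
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(m > 0, m / other, 0.0)
    sole = (m > 0) & (other == 0)
    f = np.where(sole, 1.0, f)
    return f, sole


def pto_ramet_day(matrix: DailyFloralMatrix) -> pd.DataFrame:
    """Pollen-transfer opportunity per ramet-day.

    K = f_male x (open female flowers the same day on all ramets outside
    the focal ramet's genet).  Long table (ramet_id, day, f_male, K,
    sole_donor).
    """
    f, sole = _male_fraction_arrays(matrix)
    _, ind = matrix.genet_indicator()
    fem_by_genet = ind @ matrix.female            # G x D
    fem_total = matrix.female.sum(axis=0)          # D
    # per ramet: female flowers on other genets = total - own genet's
    own = ind.T @ fem_by_genet                     # R x D (per-ramet own-genet female)
    fem_other = fem_total[None, :] - own
    k = f * fem_other
    return _long(matrix, {"f_male": f, "K": k, "sole_donor": sole})


def pto_genet(matrix: DailyFloralMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genet PTO: daily ``K_day`` and season totals ``K_g``.

    Returns (daily, totals): daily has mll_id, day, K_day for genet-days on
    which the genet had at least one open flower of either sex (genets not
    flowering that day are not observations); totals has mll_id, K_total.
    """
    per_ramet = pto_ramet_day(matrix)
    gids, ind = matrix.genet_indicator()
    k = per_ramet.pivot(index="ramet_id", columns="day", values="K") \
        .reindex(index=matrix.ramet_ids, columns=matrix.days).to_numpy()
    # accumulate sequentially in ramet order so genet sums are exactly
    # reproducible (independent of BLAS summation order)
    gpos = {g: i for i, g in enumerate(gids)}
    k_genet = np.zeros((len(gids), len(matrix.days)))
    for j, r in enumerate(matrix.ramet_ids):
        k_genet[gpos[matrix.genet_of[r]]] += k[j]
    active = (ind @ (matrix.male + matrix.female)) > 0
    rows = []
    for gi, g in enumerate(gids):
        for di, day in enumerate(matrix.days):
            if active[gi, di]:
                rows.append((g, int(day), k_genet[gi, di]))
    daily = pd.DataFrame(rows, columns=["mll_id", "day", "K_day"])
    totals = (
        daily.groupby("mll_id", as_index=False)["K_day"].sum()
        .rename(columns={"K_day": "K_total"})
    )
    return daily, totals


def _long(matrix: DailyFloralMatrix, values: dict[str, np.ndarray]) -> pd.DataFrame:
    rr, dd = np.meshgrid(
        np.arange(len(matrix.ramet_ids)), np.arange(len(matrix.days)),
        indexing="ij")
    out = pd.DataFrame({
        "ramet_id": matrix.ramet_ids[rr.ravel()],
        "day": matrix.days[dd.ravel()],
    })
    for name, arr in values.items():
        out[name] = arr.ravel()
    return out


def siring_success(
    paternity: pd.DataFrame, exclude_selfed: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Realized siring success per MLL from fractional paternity.

    ``paternity`` columns: seed_id, mll_id, pi, selfed_flag,
    pollination_day.  Returns (daily, totals): daily RS per (mll_id, day)
    and season totals per mll_id.  With ``exclude_selfed`` (the default),
    pi mass on the seed's maternal MLL is dropped before summing, so RS
    counts outcross siring only.
    """
    tab = paternity
    if exclude_selfed and len(tab):
        tab = tab[~tab["selfed_flag"].astype(bool)]
    if len(tab) == 0:
        return (
            pd.DataFrame(columns=["mll_id", "day", "RS"]),
            pd.DataFrame(columns=["mll_id", "RS_total"]),
        )
    tab = tab[tab["mll_id"] != "UNSAMPLED"]
    daily = (
        tab.groupby(["mll_id", "pollination_day"], as_index=False)["pi"].sum()
        .rename(columns={"pollination_day": "day", "pi": "RS"})
    )
    totals = (
        daily.groupby("mll_id", as_index=False)["RS"].sum()
        .rename(columns={"RS": "RS_total"})
    )
    return daily, totals
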