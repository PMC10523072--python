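"""Stage orchestration: simulate -> assign-clones -> paternity -> pto ->
siring -> trends.

Every stage reads validated CSVs, writes its outputs atomically (temp file
then rename) together with a provenance JSON (package version, seed, config
hash, input checksums), and is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from floralsync import clones as clones_mod
from floralsync import io as fio
from floralsync import matemetrics as mm
from floralsync import paternity as pat
from floralsync import synthpop
from floralsync.seasonal import PTOTrendModel, SexRatioTrendModel, SiringSuccessModel

log = logging.getLogger("floralsync")

STAGES = ["simulate", "assign-clones", "paternity", "pto", "siring", "trends"]


@dataclass
class RunConfig:
    """Run configuration for the pipeline (one YAML file).

    ``workdir`` is where every stage reads and writes its tables.
    ``population`` holds PopulationConfig overrides for the simulate stage;
    ``paternity`` holds PaternityConfig fields.  Analysis flags control the
    selfed-seed exclusion, the PTO aggregation level passed to models, and
    the zero-siring policy (exclude, or offset value for log10(RS + c)).
    """

    workdir: str = "."
    population: dict = field(default_factory=dict)
    paternity: dict = field(default_factory=dict)
    exclude_selfed: bool = True
    pto_aggregation: str = "genet"
    zero_rs_offset: float | None = None
    restrict_candidates_by_day: bool = True
    max_allelic_diff: int = 1
    rng_seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise fio.ValidationError(path, f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def path(self, name: str) -> Path:
        return Path(self.workdir) / f"{name}.csv"


def _write_atomic(df: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(".tmp")
    df.to_csv(tmp, index=False)
    os.replace(tmp, path)


def _provenance(cfg: RunConfig, stage: str, inputs: dict) -> None:
    fio.write_provenance(
        Path(cfg.workdir) / f"provenance_{stage}.json",
        config=asdict(cfg), seed=cfg.rng_seed, inputs=inputs)


def run_stage(stage: str, cfg: RunConfig) -> dict:
    """Run one pipeline stage; returns a small result summary dict."""
    Path(cfg.workdir).mkdir(parents=True, exist_ok=True)
    runner = {
        "simulate": _stage_simulate,
        "assign-clones": _stage_clones,
        "paternity": _stage_paternity,
        "pto": _stage_pto,
        "siring": _stage_siring,
        "trends": _stage_trends,
    }.get(stage)
    if runner is None:
        raise ValueError(f"unknown stage {stage!r}; stages: {STAGES}")
    log.info("running stage %s in %s", stage, cfg.workdir)
    return runner(cfg)


def run_all(cfg: RunConfig) -> dict:
    out = {}
    for stage in STAGES:
        out[stage] = run_stage(stage, cfg)
    return out


def _stage_simulate(cfg: RunConfig) -> dict:
    pop_cfg = synthpop.PopulationConfig(
        rng_seed=cfg.rng_seed, **cfg.population)
    ds = synthpop.simulate_dataset(pop_cfg)
    wd = Path(cfg.workdir)
    for name, df in [
        ("coordinates", ds.ramets), ("inflorescences", ds.inflorescences),
        ("phenology", ds.phenology), ("ramet_genotypes", ds.ramet_genotypes),
        ("seeds", ds.seeds), ("truth", ds.truth),
        ("allele_freqs", ds.allele_freqs),
    ]:
        _write_atomic(df, wd / f"{name}.csv")
    _provenance(cfg, "simulate", {})
    if len(ds.unpollinated):
        log.info("unpollinated female flowers on %d day(s)", len(ds.unpollinated))
    return {"n_ramets": len(ds.ramets),
            "n_genets": ds.ramets["genet_id"].nunique(),
            "n_seeds": len(ds.seeds)}


def _stage_clones(cfg: RunConfig) -> dict:
    geno = fio.read_csv(cfg.path("ramet_genotypes"), "ramet_genotypes")
    assignment = clones_mod.assign_clones(geno, max_diff=cfg.max_allelic_diff)
    _write_atomic(assignment.table, cfg.path("mll_assignments"))
    _provenance(cfg, "assign-clones",
                {"ramet_genotypes": cfg.path("ramet_genotypes")})
    return {"n_mlgs": assignment.n_mlgs, "n_mlls": assignment.n_mlls}


def _stage_paternity(cfg: RunConfig) -> dict:
    geno = fio.read_csv(cfg.path("ramet_genotypes"), "ramet_genotypes")
    seeds = fio.read_csv(cfg.path("seeds"), "seeds")
    mll = fio.read_csv(cfg.path("mll_assignments"), "mll_assignments")
    assignment = clones_mod.ClonalAssignment(
        table=mll, mlg_genotypes=_mlg_genotypes(geno, mll))
    phen = None
    if cfg.restrict_candidates_by_day and cfg.path("phenology").exists():
        phen = fio.read_csv(cfg.path("phenology"), "phenology")
    pcfg = pat.PaternityConfig(**cfg.paternity)
    table = pat.assign_paternity(
        seeds, geno, assignment, config=pcfg, restrict_by_phenology=phen)
    _write_atomic(table, cfg.path("paternity"))
    _provenance(cfg, "paternity", {
        "seeds": cfg.path("seeds"),
        "ramet_genotypes": cfg.path("ramet_genotypes"),
        "mll_assignments": cfg.path("mll_assignments")})
    n_unassigned = seeds["seed_id"].nunique() - table["seed_id"].nunique()
    if n_unassigned:
        log.info("%d seed(s) left unassigned", n_unassigned)
    return {"n_seeds_assigned": table["seed_id"].nunique(),
            "n_seeds_unassigned": n_unassigned}


def _mlg_genotypes(geno: pd.DataFrame, mll_table: pd.DataFrame) -> dict:
    ids, arr = clones_mod.genotypes_to_array(geno)
    mlg_of = dict(zip(mll_table["ramet_id"], mll_table["mlg_id"]))
    out = {}
    for rid, a in zip(ids, arr):
        mlg = mlg_of.get(rid)
        if mlg is not None and mlg not in out:
            out[mlg] = a
    return out


def _floral_matrix(cfg: RunConfig) -> mm.DailyFloralMatrix:
    phen = fio.read_csv(cfg.path("phenology"), "phenology")
    mll = fio.read_csv(cfg.path("mll_assignments"), "mll_assignments")
    genet_of = dict(zip(mll["ramet_id"], mll["mll_id"]))
    return mm.DailyFloralMatrix.from_phenology(phen, genet_of)


def _stage_pto(cfg: RunConfig) -> dict:
    matrix = _floral_matrix(cfg)
    daily, totals = mm.pto_genet(matrix)
    per_ramet = mm.pto_ramet_day(matrix)
    _write_atomic(daily, cfg.path("pto_daily"))
    _write_atomic(totals, cfg.path("pto_totals"))
    _write_atomic(per_ramet, cfg.path("pto_ramet"))
    infl = fio.read_csv(cfg.path("inflorescences"), "inflorescences")
    mll = fio.read_csv(cfg.path("mll_assignments"), "mll_assignments")
    sr = mm.sex_ratio_table(
        infl, mll_of_ramet=dict(zip(mll["ramet_id"], mll["mll_id"])))
    _write_atomic(sr, cfg.path("sex_ratios"))
    _provenance(cfg, "pto", {
        "phenology": cfg.path("phenology"),
        "mll_assignments": cfg.path("mll_assignments")})
    return {"n_genet_days": len(daily),
            "n_sole_donor_days": int(per_ramet["sole_donor"].sum())}


def _stage_siring(cfg: RunConfig) -> dict:
    paternity = fio.read_csv(cfg.path("paternity"), "paternity")
    daily, totals = mm.siring_success(
        paternity, exclude_selfed=cfg.exclude_selfed)
    _write_atomic(daily, cfg.path("siring"))
    _write_atomic(totals, cfg.path("siring_totals"))
    _provenance(cfg, "siring", {"paternity": cfg.path("paternity")})
    return {"n_sire_genets": totals["mll_id"].nunique() if len(totals) else 0}


def _stage_trends(cfg: RunConfig) -> dict:
    sr = fio.read_csv(cfg.path("sex_ratios"), "sex_ratios")
    pto_daily = fio.read_csv(cfg.path("pto_daily"), "pto_daily")
    siring = fio.read_csv(cfg.path("siring"), "siring")

    sex_fit = SexRatioTrendModel(sr).fit()
    pto_fit = PTOTrendModel(pto_daily).fit()
    siring_fit = SiringSuccessModel(
        siring, pto_daily, exclude_selfed=cfg.exclude_selfed,
        offset=cfg.zero_rs_offset).fit()

    summary = {
        "sex_ratio_trend": _trend_dict(sex_fit),
        "pto_trend": _trend_dict(pto_fit),
        "siring_model": {
            "selected": siring_fit.selected,
            "nobs": siring_fit.nobs,
            "n_genets": siring_fit.n_genets,
            "models": {
                name: {
                    "aic": m["aic"], "F": m["F"], "df_num": m["df_num"],
                    "df_den": m["df_den"], "F_p": m["F_p"],
                    "re_variance": m["re_variance"],
                    "converged": m["converged"],
                    "coefficients": m["coefficients"].to_dict("index"),
                }
                for name, m in siring_fit.models.items()
            },
        },
    }
    out = Path(cfg.workdir) / "models_summary.json"
    out.write_text(json.dumps(summary, indent=2, default=float))
    _provenance(cfg, "trends", {
        "sex_ratios": cfg.path("sex_ratios"),
        "pto_daily": cfg.path("pto_daily"),
        "siring": cfg.path("siring")})
    return summary


def _trend_dict(fit) -> dict:
    return {
        "intercept": fit.intercept,
        "intercept_se": fit.intercept_se,
        "edf": fit.edf,
        "stat_name": fit.smooth_fit.term_stat_name,
        "stat": fit.smooth_stat,
        "p": fit.smooth_p,
        "aic": fit.aic,
        "linear_aic": fit.linear_aic,
        "prefers_smooth": fit.prefers_smooth,
        "re_variance": fit.re_variance,
        "nobs": fit.nobs,
        "n_groups": fit.n_groups,
        "dropped_inner_group": fit.dropped_inner_group,
        "converged": fit.smooth_fit.converged,
    }
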