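"""CSV schemas, validation and provenance for the pipeline.

All pipeline tables are plain CSV with documented headers.  Days are
integer Julian days of year; coordinates are metres from the arena corner;
genotype columns come in pairs ``L{i}_a1``/``L{i}_a2`` with integer allele
labels and 0 meaning "no call" (a locus must carry 0 or 2 calls).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

__all__ = ["ValidationError", "validate_inputs", "read_csv", "write_provenance"]


class ValidationError(ValueError):
    """A pipeline input violates its schema; names the file and row."""

    def __init__(self, path, message, row=None):
        self.path = str(path)
        self.row = row
        loc = f"{path}" + (f" (row {row})" if row is not None else "")
        super().__init__(f"{loc}: {message}")


_REQUIRED = {
    "phenology": ["day", "ramet_id", "inflorescence_id",
                  "n_open_female", "n_open_male"],
    "coordinates": ["ramet_id", "genet_id", "x_m", "y_m"],
    "inflorescences": ["inflorescence_id", "ramet_id",
                       "first_flowering_day", "n_female", "n_male"],
    "ramet_genotypes": ["ramet_id"],
    "seeds": ["seed_id", "mother_ramet_id", "pollination_day"],
    "mll_assignments": ["ramet_id", "mlg_id", "mll_id"],
    "paternity": ["seed_id", "mll_id", "pi", "selfed_flag", "pollination_day"],
    "pto_daily": ["mll_id", "day", "K_day"],
    "siring": ["mll_id", "day", "RS"],
    "sex_ratios": ["inflorescence_id", "ramet_id", "mll_id",
                   "first_flowering_day", "n_male", "n_total"],
}


def read_csv(path, kind: str) -> pd.DataFrame:
    """Read and schema-check one pipeline table."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(path, "file not found")
    tab = pd.read_csv(path)
    _check_columns(path, tab, kind)
    _check_values(path, tab, kind)
    return tab


def _check_columns(path, tab, kind):
    req = _REQUIRED.get(kind, [])
    missing = [c for c in req if c not in tab.columns]
    if missing:
        raise ValidationError(path, f"missing column(s): {missing}")
    if kind in ("ramet_genotypes", "seeds"):
        locus_cols = [c for c in tab.columns if c.startswith("L") and "_a" in c]
        if len(locus_cols) == 0 or len(locus_cols) % 2:
            raise ValidationError(
                path, "genotype tables need paired L{i}_a1/L{i}_a2 columns")


def _check_values(path, tab, kind):
    int_cols = {
        "phenology": ["day", "n_open_female", "n_open_male"],
        "inflorescences": ["first_flowering_day", "n_female", "n_male"],
        "seeds": ["pollination_day"],
        "pto_daily": ["day"],
        "siring": ["day"],
        "sex_ratios": ["first_flowering_day", "n_male", "n_total"],
        "paternity": ["pollination_day"],
    }.get(kind, [])
    for col in int_cols:
        vals = tab[col]
        try:
            as_int = vals.astype(int)
        except (ValueError, TypeError):
            raise ValidationError(path, f"column {col} must be integer")
        if (vals != as_int).any():
            row = int((vals != as_int).idxmax())
            raise ValidationError(path, f"non-integer value in {col}", row=row)
    nonneg = {
        "phenology": ["n_open_female", "n_open_male"],
        "inflorescences": ["n_female", "n_male"],
        "pto_daily": ["K_day"],
        "siring": ["RS"],
        "sex_ratios": ["n_male", "n_total"],
    }.get(kind, [])
    for col in nonneg:
        neg = tab[col] < 0
        if neg.any():
            raise ValidationError(path, f"negative value in {col}",
                                  row=int(neg.idxmax()))
    if kind == "paternity":
        bad = (tab["pi"] < 0) | (tab["pi"] > 1 + 1e-9)
        if bad.any():
            raise ValidationError(path, "pi outside [0, 1]",
                                  row=int(bad.idxmax()))
    if kind in ("ramet_genotypes", "seeds"):
        locus_cols = sorted(c for c in tab.columns if c.startswith("L") and "_a" in c)
        loci = sorted({c.rsplit("_", 1)[0] for c in locus_cols})
        for locus in loci:
            a1 = tab[f"{locus}_a1"]
            a2 = tab[f"{locus}_a2"]
            half = (a1 == 0) != (a2 == 0)
            if half.any():
                raise ValidationError(
                    path, f"{locus} has a single allele call "
                    "(codominant loci carry 0 or 2 calls)",
                    row=int(half.idxmax()))


def validate_inputs(paths: dict) -> dict:
    """Validate a set of pipeline inputs and their referential integrity.

    ``paths`` maps table kind (see module docstring) to a CSV path.
    Returns a report dict; raises ``ValidationError`` on the first
    violation.
    """
    tables = {kind: read_csv(p, kind) for kind, p in paths.items()}
    report = {kind: {"path": str(paths[kind]), "n_rows": len(t)}
              for kind, t in tables.items()}
    geno = tables.get("ramet_genotypes")
    phen = tables.get("phenology")
    seeds = tables.get("seeds")
    if geno is not None and seeds is not None:
        known = set(geno["ramet_id"])
        orphan = ~seeds["mother_ramet_id"].isin(known)
        if orphan.any():
            raise ValidationError(
                paths["seeds"],
                f"seed references unknown mother "
                f"{seeds.loc[orphan.idxmax(), 'mother_ramet_id']!r}",
                row=int(orphan.idxmax()))
    if geno is not None and phen is not None:
        known = set(geno["ramet_id"])
        ungen = sorted(set(phen["ramet_id"]) - known)
        report["phenology"]["ramets_without_genotype"] = len(ungen)
    return report


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_provenance(path, *, config: dict, seed: int, inputs: dict) -> None:
    """Write a provenance JSON next to a stage's outputs."""
    import floralsync

    record = {
        "floralsync_version": floralsync.__version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "config": config,
        "inputs": {k: {"path": str(p), "sha256": file_checksum(p)}
                   for k, p in inputs.items() if Path(p).exists()},
    }
    Path(path).write_text(json.dumps(record, indent=2, default=str))
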