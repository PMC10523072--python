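#!/usr/bin/env python
"""Optional benchmark against the deposited field dataset.

The study's real data (ramet SSR genotypes, daily flower tallies, seed
genotypes) are deposited on figshare (DOI 10.6084/m9.figshare.23615817).
This script is *not* part of the test suite because it needs that download;
point it at a local copy to check:

* clone clustering: 210 MLGs and 169 MLLs from the deposited ramet
  genotypes (943 flowering ramets);
* phenology: peak open-flower tallies (254 male / 117 female) and their
  days (230 / 229);
* the siring-vs-PTO mixed model: a non-significant PTO effect.

Expected inputs (CSV; adapt --map if the deposited column names differ):
  genotypes.csv: ramet_id + L{i}_a1/L{i}_a2 allele columns (0 = missing)
  phenology.csv: day, ramet_id, inflorescence_id, n_open_female, n_open_male

Usage::

    python scripts/benchmark_figshare.py --data-dir path/to/figshare
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import pandas as pd

from floralsync import matemetrics as mm
from floralsync.clones import assign_clones
from floralsync.io import read_csv
from floralsync.seasonal import SiringSuccessModel


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", required=True)
    ap.add_argument("--paternity", default=None,
                    help="optional paternity.csv to run the siring model")
    args = ap.parse_args()
    d = Path(args.data_dir)
    out: dict = {}

    geno_path = d / "genotypes.csv"
    if geno_path.exists():
        geno = read_csv(geno_path, "ramet_genotypes")
        cl = assign_clones(geno)
        out["n_ramets"] = int(len(geno))
        out["n_mlgs"] = int(cl.n_mlgs)        # deposited data: 210
        out["n_mlls"] = int(cl.n_mlls)        # deposited data: 169

    phen_path = d / "phenology.csv"
    if phen_path.exists():
        phen = read_csv(phen_path, "phenology")
        daily = phen.groupby("day")[["n_open_female", "n_open_male"]].sum()
        out["peak_male_flowers"] = int(daily.n_open_male.max())      # 254
        out["peak_male_day"] = int(daily.n_open_male.idxmax())       # 230
        out["peak_female_flowers"] = int(daily.n_open_female.max())  # 117
        out["peak_female_day"] = int(daily.n_open_female.idxmax())   # 229

        if geno_path.exists() and args.paternity:
            pt = pd.read_csv(args.paternity)
            mll_of = cl.mll_of_ramet()
            matrix = mm.DailyFloralMatrix.from_phenology(phen, mll_of)
            pto_daily, _ = mm.pto_genet(matrix)
            siring, _ = mm.siring_success(pt)
            fit = SiringSuccessModel(siring, pto_daily).fit()
            c = fit.coef("pto", "K_day")
            out["siring_pto_F"] = fit.models["pto"]["F"]
            out["siring_pto_p"] = c["p"]

    if not out:
        raise SystemExit(f"no recognized tables under {d}")
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
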