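"""Clone assignment from codominant multilocus genotypes.

Ramets are first grouped into multilocus genotypes (MLGs: identical allele
calls and identical missingness) and MLGs are then clustered into multilocus
lineages (MLLs, taken as genets) by single-linkage over the allelic-distance
graph: two MLGs belong to the same MLL when they are connected through pairs
differing by at most ``max_diff`` alleles in total (default 1), which absorbs
single somatic mutations and single mistyped alleles into the parent clone.

Distance between two genotypes is summed over loci scored in both:
per locus, ``2 - |multiset intersection of the two allele pairs|``
(0 identical, 1 one shared allele, 2 disjoint).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["allelic_distance", "group_mlgs", "build_mlls", "assign_clones",
           "ClonalAssignment", "genotypes_to_array"]

MISSING = 0  # allele label used for "no call" in genotype tables


@dataclass
class ClonalAssignment:
    """Ramet -> MLG -> MLL mapping plus one representative genotype per MLG.

    ``table`` has columns ramet_id, mlg_id, mll_id.  ``mlg_genotypes`` maps
    mlg_id to the (n_loci, 2) allele array shared by the MLG's members.
    """

    table: pd.DataFrame
    mlg_genotypes: dict[str, np.ndarray]

    @property
    def n_mlgs(self) -> int:
        return self.table["mlg_id"].nunique()

    @property
    def n_mlls(self) -> int:
        return self.table["mll_id"].nunique()

    def mll_of_ramet(self) -> dict[str, str]:
        return dict(zip(self.table["ramet_id"], self.table["mll_id"]))


def genotypes_to_array(genotypes: pd.DataFrame, id_col: str = "ramet_id"):
    """Convert a wide genotype table to (ids, (n, n_loci, 2) int array).

    Locus columns are ``L{i}_a1``/``L{i}_a2``; allele 0 means missing.
    Pairs are sorted per locus so allele order never matters; a locus with
    exactly one called allele is treated as missing (codominant diploid data
    must carry 0 or 2 calls).
    """
    locus_cols = [c for c in genotypes.columns if c != id_col]
    if len(locus_cols) % 2 != 0:
        raise ValueError("genotype table must have paired allele columns")
    arr = genotypes[locus_cols].to_numpy(dtype=int).reshape(len(genotypes), -1, 2)
    arr = np.sort(arr, axis=2)
    half = (arr == MISSING).sum(axis=2) == 1
    arr[half] = MISSING
    return genotypes[id_col].to_numpy(), arr


def allelic_distance(g1: np.ndarray, g2: np.ndarray) -> int:
    """Total allelic distance between two genotypes over shared scored loci.

    Parameters are (n_loci, 2) arrays of allele labels with 0 = missing.
    Loci missing in either genotype are skipped.  Raises ``ValueError`` if
    no locus is scored in both (the comparison would be vacuous).
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape:
        raise ValueError("genotypes must share the same locus set")
    ok = (g1[:, 0] != MISSING) & (g2[:, 0] != MISSING)
    if not ok.any():
        raise ValueError("no locus scored in both genotypes")
    return int(_pair_dist(g1[ok], g2[ok]))


def _pair_dist(a: np.ndarray, b: np.ndarray) -> int:
    """Sum over loci of 2 - multiset intersection, pairs pre-sorted."""
    a = np.sort(a, axis=1)
    b = np.sort(b, axis=1)
    # multiset intersection of two sorted pairs: aligned positional matches
    # count fully; otherwise a single cross match, e.g. (x,y) vs (y,z)
    eq_same = (a == b).sum(axis=1)
    cross = (a[:, 0] == b[:, 1]) | (a[:, 1] == b[:, 0])
    inter = np.where(eq_same > 0, eq_same, np.where(cross, 1, 0))
    return int((2 - inter).sum())


def group_mlgs(genotypes: pd.DataFrame, id_col: str = "ramet_id") -> pd.DataFrame:
    """Group ramets into MLGs (identical calls and identical missingness).

    Returns a table (ramet_id, mlg_id).  MLG ids are canonical: MLGs are
    numbered by the lexicographically smallest member ramet id, so permuting
    input rows never changes the labelling.
    """
    if len(genotypes) == 0:
        raise ValueError("need at least one genotype")
    ids, arr = genotypes_to_array(genotypes, id_col)
    keys = [tuple(a.ravel()) for a in arr]
    groups: dict[tuple, list[str]] = {}
    for rid, key in zip(ids, keys):
        groups.setdefault(key, []).append(rid)
    reps = sorted(groups.items(), key=lambda kv: min(kv[1]))
    rows = []
    for i, (_, members) in enumerate(reps):
        mlg = f"MLG{i + 1:03d}"
        rows.extend((rid, mlg) for rid in members)
    out = pd.DataFrame(rows, columns=[id_col, "mlg_id"])
    return out.set_index(id_col).loc[ids].reset_index()


def build_mlls(
    mlg_table: pd.DataFrame,
    mlg_genotypes: dict[str, np.ndarray],
    max_diff: int = 1,
) -> pd.DataFrame:
    """Cluster MLGs into MLLs by transitive closure of distance <= max_diff.

    ``mlg_table`` maps ramets to MLG ids; ``mlg_genotypes`` carries one
    genotype per MLG.  Returns (mlg_id, mll_id) with canonical MLL ids
    (numbered by the smallest member ramet id across the component).
    """
    if max_diff < 0:
        raise ValueError("max_diff must be >= 0")
    mlg_ids = sorted(mlg_genotypes)
    g = nx.Graph()
    g.add_nodes_from(mlg_ids)
    for i, mi in enumerate(mlg_ids):
        gi = mlg_genotypes[mi]
        for mj in mlg_ids[i + 1:]:
            try:
                d = allelic_distance(gi, mlg_genotypes[mj])
            except ValueError:  # disjoint scored loci: never linked
                continue
            if d <= max_diff:
                g.add_edge(mi, mj)
    min_ramet = mlg_table.groupby("mlg_id")[mlg_table.columns[0]].min()
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: min(min_ramet.get(m, m) for m in c),
    )
    rows = []
    for k, comp in enumerate(comps):
        mll = f"MLL{k + 1:03d}"
        rows.extend((m, mll) for m in comp)
    return pd.DataFrame(rows, columns=["mlg_id", "mll_id"])


def assign_clones(
    genotypes: pd.DataFrame, max_diff: int = 1, id_col: str = "ramet_id"
) -> ClonalAssignment:
    """Full clone assignment: ramets -> MLGs -> MLLs."""
    ids, arr = genotypes_to_array(genotypes, id_col)
    mlg_table = group_mlgs(genotypes, id_col)
    rep_geno: dict[str, np.ndarray] = {}
    for rid, mlg, a in zip(mlg_table[id_col], mlg_table["mlg_id"], arr):
        rep_geno.setdefault(mlg, a)
    mll_table = build_mlls(mlg_table, rep_geno, max_diff=max_diff)
    table = mlg_table.merge(mll_table, on="mlg_id", how="left")
    return ClonalAssignment(table=table, mlg_genotypes=rep_geno)
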