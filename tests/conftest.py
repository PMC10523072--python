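"""Shared fixtures: scaled-down synthetic populations and genotype helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from floralsync.synthpop import PopulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> PopulationConfig:
    """A fast population: same biology, fewer genets."""
    return PopulationConfig(n_genets=60, rng_seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def clean_dataset():
    """No somatic variants, no mistyping: observed = genet genotypes."""
    return simulate_dataset(PopulationConfig(
        n_genets=60, somatic_mlg_rate=0.0, genotyping_error=0.0, rng_seed=11))


def make_genotype_frame(genos: dict[str, list[tuple[int, int]]]) -> pd.DataFrame:
    """Build a wide genotype table from {ramet_id: [(a1, a2) per locus]}."""
    rows = []
    for rid, loci in genos.items():
        row = {"ramet_id": rid}
        for i, (a1, a2) in enumerate(loci):
            row[f"L{i + 1}_a1"] = a1
            row[f"L{i + 1}_a2"] = a2
        rows.append(row)
    return pd.DataFrame(rows)


def random_genotype_table(
    rng: np.random.Generator, n: int, n_loci: int = 7, n_alleles: int = 6,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Random diploid genotypes with small allele pools (forces collisions)."""
    genos = {}
    for i in range(n):
        loci = []
        for _ in range(n_loci):
            if missing_rate and rng.random() < missing_rate:
                loci.append((0, 0))
            else:
                a, b = sorted(rng.integers(100, 100 + 2 * n_alleles, size=2))
                loci.append((int(a), int(b)))
        genos[f"R{i:03d}"] = loci
    return make_genotype_frame(genos)
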