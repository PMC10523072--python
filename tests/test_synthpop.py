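"""Simulator invariants: protogyny, conservation, determinism, mating law."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from floralsync.synthpop import (
    ConfigurationError,
    PopulationConfig,
    generate_genotypes,
    generate_phenology,
    generate_population,
    simulate_dataset,
    simulate_mating,
)
from tests.conftest import make_genotype_frame


class TestPopulationStructure:
    def test_paper_like_population_size_and_clonal_structure(self):
        """~169 genets give roughly 943 ramets, ~40% singletons, max 35."""
        totals, singles, maxs = [], [], []
        for seed in range(8):
            pop = generate_population(PopulationConfig(rng_seed=seed))
            sizes = pop.groupby("genet_id").size()
            totals.append(sizes.sum())
            singles.append((sizes == 1).mean())
            maxs.append(sizes.max())
        assert 750 <= np.mean(totals) <= 1150
        assert 0.30 <= np.mean(singles) <= 0.50
        assert max(maxs) <= 35

    def test_degenerate_single_genet(self):
        cfg = PopulationConfig(n_genets=1, singleton_prob=1.0, rng_seed=3)
        pop = generate_population(cfg)
        assert len(pop) == 1

    def test_determinism_same_seed(self):
        a = simulate_dataset(PopulationConfig(n_genets=25, rng_seed=5))
        b = simulate_dataset(PopulationConfig(n_genets=25, rng_seed=5))
        for name in ("ramets", "phenology", "ramet_genotypes", "seeds", "truth"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))

    def test_clonemates_are_spatially_clustered(self):
        pop = generate_population(PopulationConfig(rng_seed=2))
        merged = pop.merge(
            pop.groupby("genet_id")[["x_m", "y_m"]].transform("mean")
            .rename(columns={"x_m": "cx", "y_m": "cy"}),
            left_index=True, right_index=True)
        within = np.hypot(merged.x_m - merged.cx, merged.y_m - merged.cy)
        sizes = pop.groupby("genet_id")["ramet_id"].transform("size")
        # within-genet spread is far below the arena scale
        assert within[sizes > 1].mean() < 5.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            PopulationConfig(season=(240, 199))
        with pytest.raises(ConfigurationError):
            PopulationConfig(singleton_prob=1.5)
        with pytest.raises(ConfigurationError):
            PopulationConfig(kernel_scale=-1.0)


class TestPhenology:
    def test_protogyny_and_conservation_exhaustive(self, small_dataset):
        """Every inflorescence: all female days precede all male days, and
        daily open counts sum to the inflorescence totals."""
        phen = small_dataset.phenology
        infl = small_dataset.inflorescences.set_index("inflorescence_id")
        for iid, sub in phen.groupby("inflorescence_id"):
            fdays = sub.loc[sub.n_open_female > 0, "day"]
            mdays = sub.loc[sub.n_open_male > 0, "day"]
            if len(fdays) and len(mdays):
                assert fdays.max() < mdays.min()
            assert sub.n_open_female.sum() == infl.loc[iid, "n_female"]
            assert sub.n_open_male.sum() == infl.loc[iid, "n_male"]

    def test_flowers_open_within_season(self, small_dataset):
        first, last = small_dataset.config.season
        assert small_dataset.phenology.day.between(first, last).all()

    def test_female_display_precedes_male_display(self):
        """Protogyny at the inflorescence level: the flower-weighted mean
        female day precedes the mean male day in every replicate, and the
        population peak days nearly coincide."""
        near = 0
        for seed in range(20):
            cfg = PopulationConfig(n_genets=80, rng_seed=100 + seed)
            pop = generate_population(cfg)
            phen, _ = generate_phenology(pop, cfg)
            daily = phen.groupby("day")[["n_open_female", "n_open_male"]].sum()
            f_mean = np.average(daily.index, weights=daily.n_open_female)
            m_mean = np.average(daily.index, weights=daily.n_open_male)
            assert f_mean < m_mean
            near += abs(
                int(daily.n_open_male.idxmax())
                - int(daily.n_open_female.idxmax())) <= 5
        assert near >= 18


class TestGenotypes:
    def test_no_noise_mlg_count_equals_genets(self, clean_dataset):
        obs = clean_dataset.ramet_genotypes
        keys = obs.drop(columns="ramet_id").apply(tuple, axis=1)
        n_genets = clean_dataset.ramets.genet_id.nunique()
        assert keys.nunique() == n_genets

    def test_somatic_variants_are_distance_one(self):
        cfg = PopulationConfig(
            n_genets=40, somatic_mlg_rate=0.3, genotyping_error=0.0,
            rng_seed=9)
        pop = generate_population(cfg)
        obs, true_df, _ = generate_genotypes(pop, cfg)
        from floralsync.clones import allelic_distance, genotypes_to_array

        ids, arr = genotypes_to_array(obs)
        genet_of = dict(zip(pop.ramet_id, pop.genet_id))
        by_genet = {}
        for rid, a in zip(ids, arr):
            by_genet.setdefault(genet_of[rid], []).append(a)
        n_mlgs = len({tuple(a.ravel()) for a in arr})
        assert n_mlgs >= pop.genet_id.nunique()
        for members in by_genet.values():
            ref = members[0]
            for other in members[1:]:
                assert allelic_distance(ref, other) <= 2  # two variants max

    def test_allele_frequencies_match_generating_law(self):
        """Genet-level allele draws are consistent with the published
        frequencies (chi-square on pooled counts at a fixed seed)."""
        cfg = PopulationConfig(
            n_genets=300, somatic_mlg_rate=0.0, genotyping_error=0.0,
            alleles_per_locus=8, rng_seed=21)
        pop = generate_population(cfg)
        obs, _, af = generate_genotypes(pop, cfg)
        genet_rows = obs.drop_duplicates(
            subset=obs.columns.drop("ramet_id").tolist())
        for locus in [f"L{i}" for i in (1, 4, 7)]:
            alleles = pd.concat(
                [genet_rows[f"{locus}_a1"], genet_rows[f"{locus}_a2"]])
            freq = af[af.locus == locus].set_index("allele")["freq"]
            counts = alleles.value_counts().reindex(freq.index, fill_value=0)
            _, p = stats.chisquare(counts, freq * counts.sum())
            assert p > 1e-3


class TestMating:
    @staticmethod
    def _two_donor_setup(n_female=2000):
        ramets = pd.DataFrame({
            "ramet_id": ["M", "D1", "D2"],
            "genet_id": ["GM", "GA", "GB"],
            "x_m": [0.0, 5.0, 10.0], "y_m": [0.0, 0.0, 0.0]})
        phen = pd.DataFrame({
            "day": [200, 200, 200],
            "ramet_id": ["M", "D1", "D2"],
            "inflorescence_id": ["I1", "I2", "I3"],
            "n_open_female": [n_female, 0, 0],
            "n_open_male": [0, 3, 1]})
        geno = make_genotype_frame({
            "M": [(100, 100)] * 7,
            "D1": [(102, 102)] * 7,
            "D2": [(104, 104)] * 7})
        return ramets, phen, geno

    def test_uniform_kernel_sire_shares_proportional_to_male_flowers(self):
        """Two donors with 3 vs 1 open male flowers sire ~75% / 25%."""
        ramets, phen, geno = self._two_donor_setup()
        cfg = PopulationConfig(
            n_genets=3, kernel_scale=None, seed_sample_fraction=1.0,
            genotyping_error=0.0, rng_seed=13)
        seeds, truth, _ = simulate_mating(phen, geno, ramets, cfg)
        share = (truth.true_sire_ramet == "D1").mean()
        n = len(truth)
        ci = 2.576 * np.sqrt(0.75 * 0.25 / n)
        assert abs(share - 0.75) < ci
        assert n == 2000

    def test_single_donor_monopoly(self):
        ramets, phen, geno = self._two_donor_setup(n_female=50)
        phen.loc[phen.ramet_id == "D2", "n_open_male"] = 0
        cfg = PopulationConfig(
            n_genets=3, seed_sample_fraction=1.0, genotyping_error=0.0,
            rng_seed=13)
        _, truth, _ = simulate_mating(phen, geno, ramets, cfg)
        assert (truth.true_sire_ramet == "D1").all()

    def test_day_without_donors_logs_unpollinated(self):
        ramets, phen, geno = self._two_donor_setup(n_female=10)
        phen["n_open_male"] = 0
        cfg = PopulationConfig(
            n_genets=3, seed_sample_fraction=1.0, rng_seed=13)
        seeds, truth, unpoll = simulate_mating(phen, geno, ramets, cfg)
        assert len(truth) == 0
        assert unpoll.n_unpollinated.sum() == 10

    def test_restricted_kernel_shortens_mating_distance(self):
        near, far = [], []
        for seed in range(5):
            for scale, acc in ((1.0, near), (None, far)):
                ds = simulate_dataset(PopulationConfig(
                    n_genets=50, kernel_scale=scale, rng_seed=300 + seed))
                coords = ds.ramets.set_index("ramet_id")[["x_m", "y_m"]]
                t = ds.truth.merge(
                    ds.seeds[["seed_id", "mother_ramet_id"]], on="seed_id")
                d = np.hypot(
                    coords.loc[t.mother_ramet_id].x_m.to_numpy()
                    - coords.loc[t.true_sire_ramet].x_m.to_numpy(),
                    coords.loc[t.mother_ramet_id].y_m.to_numpy()
                    - coords.loc[t.true_sire_ramet].y_m.to_numpy())
                acc.append(d.mean())
        assert np.mean(near) < np.mean(far)

    def test_truth_sires_had_open_male_flowers(self, small_dataset):
        phen = small_dataset.phenology
        male_by_day = phen[phen.n_open_male > 0].groupby("day")[
            "ramet_id"].agg(set)
        for _, row in small_dataset.truth.iterrows():
            assert row.true_sire_ramet in male_by_day[row.pollination_day]

    def test_selfed_flag_matches_genet_identity(self, small_dataset):
        genet_of = dict(zip(
            small_dataset.ramets.ramet_id, small_dataset.ramets.genet_id))
        t = small_dataset.truth.merge(
            small_dataset.seeds[["seed_id", "mother_ramet_id"]], on="seed_id")
        expect = [
            genet_of[m] == genet_of[s]
            for m, s in zip(t.mother_ramet_id, t.true_sire_ramet)]
        assert list(t.is_selfed) == expect

    def test_selfing_increases_with_genet_size(self):
        """At a fixed restricted kernel, bigger clones mean more
        geitonogamy (monotone over a 3-point sweep of mean genet size)."""
        means = []
        for nb_mean in (1.0, 6.0, 20.0):
            fr = []
            for rep in range(10):
                ds = simulate_dataset(PopulationConfig(
                    n_genets=40, singleton_prob=0.1,
                    genet_size_nb_mean=nb_mean, kernel_scale=2.0,
                    rng_seed=500 + rep))
                if len(ds.truth):
                    fr.append(ds.truth.is_selfed.mean())
            means.append(np.mean(fr))
        assert means[0] < means[1] < means[2]
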