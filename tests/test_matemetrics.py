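"""PTO index, sex ratios and siring aggregation against naive-loop oracles."""

import numpy as np
import pandas as pd
import pytest

from floralsync.matemetrics import (
    DailyFloralMatrix,
    inflorescence_sex_ratio,
    male_fraction,
    pto_genet,
    pto_ramet_day,
    sex_ratio_table,
    siring_success,
)


def make_matrix(female, male, genets):
    """female/male: {ramet: {day: count}}; genets: {ramet: genet}."""
    ramets = sorted(genets)
    days = sorted({d for tab in (female, male)
                   for per in tab.values() for d in per})
    f = np.zeros((len(ramets), len(days)))
    m = np.zeros((len(ramets), len(days)))
    for arr, tab in ((f, female), (m, male)):
        for i, r in enumerate(ramets):
            for j, d in enumerate(days):
                arr[i, j] = tab.get(r, {}).get(d, 0)
    return DailyFloralMatrix(
        ramet_ids=np.array(ramets), days=np.array(days),
        female=f, male=m, genet_of=dict(genets))


def naive_pto(matrix: DailyFloralMatrix):
    """Triple-loop reference implementation of f, K_ij and K_g."""
    R, D = matrix.male.shape
    f = np.zeros((R, D))
    k = np.zeros((R, D))
    for j in range(R):
        for d in range(D):
            nm = matrix.male[j, d]
            others = sum(matrix.male[l, d] for l in range(R) if l != j)
            if nm == 0:
                f[j, d] = 0.0
            elif others == 0:
                f[j, d] = 1.0
            else:
                f[j, d] = nm / others
            g = matrix.genet_of[matrix.ramet_ids[j]]
            fem = sum(
                matrix.female[i, d] for i in range(R)
                if matrix.genet_of[matrix.ramet_ids[i]] != g)
            k[j, d] = f[j, d] * fem
    kg = {}
    for gi in sorted({matrix.genet_of[r] for r in matrix.ramet_ids}):
        kg[gi] = np.zeros(D)
        for j in range(R):
            if matrix.genet_of[matrix.ramet_ids[j]] == gi:
                kg[gi] += k[j]
    return f, k, kg


class TestSexRatio:
    def test_arithmetic(self):
        assert inflorescence_sex_ratio(6, 9) == pytest.approx(0.667, abs=5e-4)
        assert inflorescence_sex_ratio(0, 4) == 0.0
        assert inflorescence_sex_ratio(4, 4) == 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            inflorescence_sex_ratio(0, 0)

    def test_table_drops_flowerless_inflorescences(self):
        infl = pd.DataFrame({
            "inflorescence_id": ["I1", "I2"],
            "ramet_id": ["R1", "R2"],
            "genet_id": ["G1", "G2"],
            "first_flowering_day": [200, 201],
            "n_female": [2, 0], "n_male": [3, 0]})
        out = sex_ratio_table(infl)
        assert list(out.inflorescence_id) == ["I1"]
        assert out.sex_ratio.iloc[0] == pytest.approx(0.6)


class TestMaleFraction:
    def test_basic_fraction(self):
        m = make_matrix(
            female={}, male={"a": {1: 2}, "b": {1: 3}},
            genets={"a": "G1", "b": "G2"})
        f = male_fraction(m).set_index("ramet_id")
        assert f.loc["a", "f_male"] == pytest.approx(2 / 3)
        assert f.loc["b", "f_male"] == pytest.approx(3 / 2)

    def test_zero_male_gives_zero(self):
        m = make_matrix(
            female={"a": {1: 5}}, male={"b": {1: 3}},
            genets={"a": "G1", "b": "G2"})
        f = male_fraction(m).set_index("ramet_id")
        assert f.loc["a", "f_male"] == 0.0
        assert not f.loc["a", "sole_donor"]

    def test_sole_donor_convention(self):
        m = make_matrix(
            female={"a": {1: 5}}, male={"b": {1: 4}},
            genets={"a": "G1", "b": "G2"})
        f = male_fraction(m).set_index("ramet_id")
        assert f.loc["b", "f_male"] == 1.0
        assert bool(f.loc["b", "sole_donor"])


class TestPTO:
    def test_hand_value(self):
        """f = 2/3 with 4 female flowers on other genets: K = 2.667."""
        m = make_matrix(
            female={"c": {1: 4}},
            male={"a": {1: 2}, "b": {1: 3}},
            genets={"a": "G1", "b": "G2", "c": "G3"})
        k = pto_ramet_day(m).set_index("ramet_id")
        assert k.loc["a", "K"] == pytest.approx(2 / 3 * 4)

    def test_self_genet_females_excluded(self):
        m = make_matrix(
            female={"a2": {1: 7}},
            male={"a": {1: 2}, "b": {1: 1}},
            genets={"a": "G1", "a2": "G1", "b": "G2"})
        k = pto_ramet_day(m).set_index("ramet_id")
        assert k.loc["a", "K"] == 0.0        # only own-genet females open
        assert k.loc["b", "K"] == pytest.approx(0.5 * 7)

    def test_no_females_anywhere(self):
        m = make_matrix(
            female={}, male={"a": {1: 2}, "b": {1: 3}},
            genets={"a": "G1", "b": "G2"})
        assert (pto_ramet_day(m)["K"] == 0).all()

    def test_genet_additivity(self):
        m = make_matrix(
            female={"c": {1: 10}},
            male={"a1": {1: 1}, "a2": {1: 2}, "b": {1: 2}},
            genets={"a1": "G1", "a2": "G1", "b": "G2", "c": "G3"})
        per_ramet = pto_ramet_day(m).set_index("ramet_id")
        daily, totals = pto_genet(m)
        g1 = daily[daily.mll_id == "G1"].K_day.iloc[0]
        assert g1 == pytest.approx(
            per_ramet.loc["a1", "K"] + per_ramet.loc["a2", "K"])
        assert totals.set_index("mll_id").loc["G1", "K_total"] \
            == pytest.approx(g1)

    def test_vectorized_equals_naive_oracle(self):
        """Exact agreement with the triple-loop reference on random
        instances (counts are integers, so sums are exact in floats)."""
        rng = np.random.default_rng(99)
        for _ in range(50):
            R = int(rng.integers(2, 15))
            D = int(rng.integers(1, 6))
            genets = {f"r{i}": f"g{rng.integers(1, max(2, R // 2))}"
                      for i in range(R)}
            female = {f"r{i}": {d: int(rng.integers(0, 5)) for d in range(D)}
                      for i in range(R)}
            male = {f"r{i}": {d: int(rng.integers(0, 5)) for d in range(D)}
                    for i in range(R)}
            m = make_matrix(female, male, genets)
            f_o, k_o, kg_o = naive_pto(m)
            got = pto_ramet_day(m)
            f_got = got.pivot(index="ramet_id", columns="day", values="f_male") \
                .loc[m.ramet_ids, m.days].to_numpy()
            k_got = got.pivot(index="ramet_id", columns="day", values="K") \
                .loc[m.ramet_ids, m.days].to_numpy()
            assert np.array_equal(f_got, f_o)
            assert np.array_equal(k_got, k_o)
            daily, _ = pto_genet(m)
            for g, kvals in kg_o.items():
                sub = daily[daily.mll_id == g].set_index("day")["K_day"]
                for di, day in enumerate(m.days):
                    if day in sub.index:
                        assert sub[day] == kvals[di]

    def test_metamorphic_self_exclusion(self):
        """Adding female flowers to the focal genet never changes its K."""
        base = make_matrix(
            female={"c": {1: 4}},
            male={"a": {1: 2}, "b": {1: 3}},
            genets={"a": "G1", "b": "G2", "c": "G3"})
        more = make_matrix(
            female={"c": {1: 4}, "a": {1: 9}},
            male={"a": {1: 2}, "b": {1: 3}},
            genets={"a": "G1", "b": "G2", "c": "G3"})
        k0 = pto_ramet_day(base).set_index("ramet_id").loc["a", "K"]
        k1 = pto_ramet_day(more).set_index("ramet_id").loc["a", "K"]
        assert k0 == k1

    def test_monotone_in_nonself_female_flowers(self):
        """An extra female flower on another genet never decreases K of a
        ramet with positive male fraction."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            female = {"c": {1: int(rng.integers(0, 6))}}
            male = {"a": {1: int(rng.integers(1, 5))},
                    "b": {1: int(rng.integers(0, 5))}}
            genets = {"a": "G1", "b": "G2", "c": "G3"}
            k0 = pto_ramet_day(make_matrix(female, male, genets)) \
                .set_index("ramet_id")["K"]
            female["c"][1] += 1
            k1 = pto_ramet_day(make_matrix(female, male, genets)) \
                .set_index("ramet_id")["K"]
            assert k1["a"] >= k0["a"]


class TestSiringSuccess:
    @staticmethod
    def _pat(rows):
        return pd.DataFrame(
            rows, columns=["seed_id", "mll_id", "pi", "selfed_flag",
                           "pollination_day"])

    def test_sums_outcross_pi(self):
        pat = self._pat([
            ("s1", "M1", 0.5, False, 210),
            ("s2", "M1", 0.25, False, 210),
            ("s2", "M2", 0.75, False, 210)])
        daily, totals = siring_success(pat)
        assert daily.set_index(["mll_id", "day"]).loc[("M1", 210), "RS"] \
            == pytest.approx(0.75)
        assert totals.set_index("mll_id").loc["M2", "RS_total"] \
            == pytest.approx(0.75)

    def test_selfed_mass_excluded(self):
        pat = self._pat([("s1", "M1", 0.9, True, 210)])
        daily, totals = siring_success(pat, exclude_selfed=True)
        assert len(daily) == 0
        daily2, _ = siring_success(pat, exclude_selfed=False)
        assert daily2.RS.iloc[0] == pytest.approx(0.9)

    def test_empty_paternity_table(self):
        daily, totals = siring_success(self._pat([]))
        assert len(daily) == 0 and len(totals) == 0

    def test_daily_values_sum_to_season_total(self):
        pat = self._pat([
            ("s1", "M1", 1.0, False, 210),
            ("s2", "M1", 0.4, False, 215),
            ("s3", "M1", 0.6, False, 215)])
        daily, totals = siring_success(pat)
        assert totals.RS_total.iloc[0] == pytest.approx(daily.RS.sum())
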