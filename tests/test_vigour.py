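"""Physiological indices, correlation/ANOVA statistics and ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from peavigour import (
    ReflectanceRecord,
    WaterLog,
    ewue,
    ndvi,
    one_way_anova,
    pearson_matrix,
    rank_genotypes,
    simulate_field_ndvi,
)

from oracles import longhand_anova, longhand_pearson


class TestEwue:
    def test_ratio(self):
        assert ewue(100.0, WaterLog("p1", 2.0)) == pytest.approx(50.0)
        assert ewue(0.0, 1.5) == 0.0

    def test_published_scale_inversion(self):
        # the printed Alma means: EB 370.40 kPix at eWUE 189.34 imply the
        # unpublished water total 370.40 / 189.34 kg
        water = 370.40 / 189.34
        assert ewue(370.40, water) == pytest.approx(189.34)

    def test_rejects_nonpositive_water(self):
        with pytest.raises(ValueError):
            ewue(10.0, 0.0)
        with pytest.raises(ValueError):
            WaterLog("p", -1.0)


class TestNdvi:
    def test_examples(self):
        assert ndvi(ReflectanceRecord("p", "g", 0.3, 0.3)) == 0.0
        assert ndvi(ReflectanceRecord("p", "g", 0.0, 0.4)) == 1.0
        assert ndvi(ReflectanceRecord("p", "g", 0.2, 0.6)) == pytest.approx(0.5)

    @given(
        r670=st.floats(0.0, 1.0),
        r760=st.floats(0.0, 1.0),
    )
    def test_bounded_and_antisymmetric(self, r670, r760):
        if r670 + r760 == 0:
            return
        v = ndvi((r760, r670))
        assert -1.0 <= v <= 1.0
        assert ndvi((r670, r760)) == pytest.approx(-v)

    def test_validation(self):
        with pytest.raises(ValueError):
            ReflectanceRecord("p", "g", 1.2, 0.5)
        with pytest.raises(ValueError):
            ndvi((0.0, 0.0))


class TestPearsonMatrix:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        t = pd.DataFrame({"x": x, "y": 2 * x + 1, "z": -x})
        res = pearson_matrix(t)
        assert res.r.loc["x", "y"] == pytest.approx(1.0)
        assert res.r.loc["x", "z"] == pytest.approx(-1.0)
        assert res.stars.loc["x", "y"] == "***"

    def test_matches_longhand_quotient(self):
        rng = np.random.default_rng(5)
        t = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        res = pearson_matrix(t)
        for i in "abc":
            for j in "abc":
                if i != j:
                    assert res.r.loc[i, j] == pytest.approx(
                        longhand_pearson(t[i], t[j])
                    )

    def test_symmetry_unit_diagonal_affine_invariance(self):
        rng = np.random.default_rng(6)
        t = pd.DataFrame(rng.normal(size=(15, 3)), columns=list("abc"))
        res = pearson_matrix(t)
        assert np.allclose(res.r.values, res.r.values.T)
        assert np.allclose(np.diag(res.r.values), 1.0)
        res2 = pearson_matrix(t.assign(a=3.0 * t["a"] + 7.0))
        assert np.allclose(res.r.values, res2.r.values)

    def test_zero_variance_column_yields_nan_with_warning(self):
        t = pd.DataFrame({"a": np.arange(5.0), "b": np.ones(5)})
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pearson_matrix(t)
        assert np.isnan(res.r.loc["a", "b"])

    def test_pairwise_complete_and_minimum_rows(self):
        t = pd.DataFrame({"a": [1.0, 2, 3, np.nan], "b": [2.0, 4, 7, 9]})
        assert pearson_matrix(t).n.loc["a", "b"] == 3
        t2 = pd.DataFrame({"a": [1.0, 2, np.nan, np.nan], "b": [2.0, 4, 7, 9]})
        with pytest.raises(ValueError, match="complete rows"):
            pearson_matrix(t2)


class TestOneWayAnova:
    def test_two_group_hand_arithmetic(self):
        res = one_way_anova({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert res.f == pytest.approx(13.5)
        assert res.f == pytest.approx(longhand_anova([[1, 2, 3], [4, 5, 6]]))

    def test_matches_longhand_on_many_groups(self):
        rng = np.random.default_rng(2)
        groups = {f"g{i}": rng.normal(i * 0.5, 1.0, size=6) for i in range(5)}
        res = one_way_anova(groups)
        assert res.f == pytest.approx(longhand_anova(list(groups.values())))

    def test_two_groups_f_is_squared_pooled_t(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 8), rng.normal(0.7, 1, 8)
        res = one_way_anova({"a": a, "b": b})
        t = sps.ttest_ind(a, b).statistic
        assert res.f == pytest.approx(t**2)

    def test_null_case_small_f(self):
        rng = np.random.default_rng(4)
        res = one_way_anova({k: 5.0 + rng.normal(0, 1, 10) for k in "abcd"})
        assert res.p > 0.05

    def test_degenerate_zero_mse_contract(self):
        res = one_way_anova({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert np.isinf(res.f) and res.p == 0.0
        same = one_way_anova({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert np.isnan(same.f) and np.isnan(same.p)

    def test_lsd_agrees_with_pairwise_t_decision(self):
        """Two group means differ by more than the LSD exactly when the
        pooled two-sample t test at df_error is significant at 5%."""
        rng = np.random.default_rng(8)
        groups = {f"g{i}": rng.normal(i * 0.4, 1.0, size=5) for i in range(6)}
        res = one_way_anova(groups)
        means = {k: np.mean(v) for k, v in groups.items()}
        keys = list(groups)
        for i, ki in enumerate(keys):
            for kj in keys[i + 1 :]:
                diff = abs(means[ki] - means[kj])
                p = 2 * sps.t.sf(diff / res.sed, res.df_error)
                assert (diff > res.lsd) == (p < 0.05)

    def test_unbalanced_warns_and_uses_harmonic_mean(self):
        with pytest.warns(UserWarning, match="harmonic"):
            res = one_way_anova({"a": [1, 2, 3, 4], "b": [4.0, 5.5]})
        n_h = 2 / (1 / 4 + 1 / 2)
        assert res.sed == pytest.approx(np.sqrt(2 * res.ms_error / n_h))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            one_way_anova({"a": [1, 2, 3]})
        with pytest.raises(ValueError):
            one_way_anova({"a": [1, 2], "b": [3.0]})


def toy_traits(eb_by_genotype, day=27, reps=4, rng=None):
    rng = rng or np.random.default_rng(0)
    rows = []
    for g, eb in eb_by_genotype.items():
        for r in range(1, reps + 1):
            rows.append((f"{g}r{r}", g, day, eb * (1 + 0.01 * rng.standard_normal())))
    return pd.DataFrame(rows, columns=["plant_id", "genotype", "das", "eb_kpix"])


class TestRankGenotypes:
    def test_dominant_genotype_ranks_first(self):
        vt = rank_genotypes(toy_traits({"A": 300.0, "B": 120.0, "C": 40.0}), 27)
        assert vt.table.index.tolist() == ["A", "B", "C"]
        assert vt.table["rank"].tolist() == [1, 2, 3]

    def test_deterministic_and_seed_free(self):
        t = toy_traits({"A": 300.0, "B": 120.0})
        a = rank_genotypes(t, 27)
        b = rank_genotypes(t, 27)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_measured_biomass_overrides_eb_ranking(self):
        t = toy_traits({"A": 300.0, "B": 120.0})
        mb = pd.DataFrame(
            {"plant_id": ["Ar1", "Ar2", "Br1", "Br2"],
             "genotype": ["A", "A", "B", "B"],
             "mb_g": [10.0, 11.0, 30.0, 31.0]}
        )
        vt = rank_genotypes(t, 27, measured_biomass=mb)
        assert vt.table.index.tolist() == ["B", "A"]

    def test_missing_genotype_dropped(self, caplog):
        t = toy_traits({"A": 300.0, "B": 120.0})
        t.loc[t["genotype"] == "B", "das"] = 20  # B absent at day 27
        with caplog.at_level("WARNING", logger="peavigour.vigour"):
            vt = rank_genotypes(t, 27)
        assert vt.table.index.tolist() == ["A"]
        assert any("missing" in m for m in caplog.messages)

    def test_ndvi_correlation_survives_link_noise(self, ref_params):
        """With an affine EB->NDVI link plus Gaussian noise the measured
        correlation should not fall far below the closed-form attenuation
        r = sigma_s / sqrt(sigma_s^2 + sigma_n^2)."""
        from peavigour import broken_stick_value

        means = {
            r.genotype: broken_stick_value(27.0, r.x_day, r.y_kpix, r.slope1, r.slope2)
            for r in ref_params.itertuples(index=False)
        }
        traits = toy_traits(means)
        lo, hi = min(means.values()), max(means.values())
        b = (0.85 - 0.2) / (hi - lo)
        noise_sd = 0.02
        recs = simulate_field_ndvi(means, (0.2 - b * lo, b), noise_sd=noise_sd, seed=1)
        vt = rank_genotypes(traits, 27, reflectance=recs)
        sigma_s = b * np.std(list(means.values()))
        expected = sigma_s / np.hypot(sigma_s, noise_sd)
        assert vt.ndvi_correlations.loc["EB", "r"] >= expected - 0.05
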