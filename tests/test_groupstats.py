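"""Assumption-routed group tests, Bonferroni correction, and correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phonoscope.groupstats import (
    StatsConfig,
    bonferroni,
    compare_groups,
    correlate_symptoms,
    participant_means,
    percent_difference,
    route_and_test,
    welch_anova_f,
)
from phonoscope.synth import synth_feature_table, synth_symptom_scores


def oneway_anova_oracle(groups):
    """Brute-force sum-of-squares decomposition for one-way ANOVA."""
    all_x = np.concatenate(groups)
    grand = all_x.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_x) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


class TestPercentDifference:
    def test_sign_convention_is_patient_minus_reference(self):
        assert percent_difference(np.array([8.37]), np.array([10.0])) == pytest.approx(-16.3)

    def test_equal_means_give_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert percent_difference(x, x) == 0.0

    def test_zero_reference_mean_is_missing(self):
        assert np.isnan(percent_difference(np.array([1.0]), np.array([0.0])))


class TestRouting:
    def test_forced_anova_matches_sum_of_squares_oracle(self):
        g1, g2 = np.array([0.0, 1.0, 2.0]), np.array([3.0, 4.0, 5.0])
        test, f, p, _ = route_and_test({"a": g1, "b": g2}, force_route="anova")
        assert test == "anova"
        assert f == pytest.approx(13.5)
        assert f == pytest.approx(oneway_anova_oracle([g1, g2]), abs=1e-9)

    def test_anova_equals_oracle_on_random_gaussian_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            g1 = rng.normal(0, 1, rng.integers(5, 30))
            g2 = rng.normal(rng.uniform(-1, 1), 1, rng.integers(5, 30))
            _, f, _, _ = route_and_test({"a": g1, "b": g2}, force_route="anova")
            assert f == pytest.approx(oneway_anova_oracle([g1, g2]), abs=1e-9)

    def test_identical_groups_are_a_null_result(self):
        g = np.arange(10.0)
        test, stat, p, _ = route_and_test({"a": g, "b": g.copy()})
        assert p >= 0.99

    def test_heavy_tailed_data_routes_to_mann_whitney(self):
        routed = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            g1 = rng.lognormal(0, 1.5, 20)
            g2 = rng.lognormal(0.3, 1.5, 20)
            test, *_ = route_and_test({"a": g1, "b": g2})
            routed += test == "mann_whitney"
        assert routed >= 18

    def test_unequal_variance_gaussians_route_to_welch(self):
        routed = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            g1 = rng.normal(0, 1.0, 30)
            g2 = rng.normal(0.5, 4.0, 30)
            test, *_ = route_and_test({"a": g1, "b": g2})
            routed += test == "welch"
        assert routed >= 12  # Shapiro occasionally trips on small samples

    def test_welch_matches_independent_implementation(self):
        # dual-route check against pingouin's Welch ANOVA
        import pingouin as pg

        rng = np.random.default_rng(3)
        g1, g2, g3 = rng.normal(0, 1, 25), rng.normal(0.5, 3, 20), rng.normal(1, 2, 30)
        f, p = welch_anova_f([g1, g2, g3])
        df = pd.DataFrame(
            {"y": np.concatenate([g1, g2, g3]),
             "g": ["a"] * 25 + ["b"] * 20 + ["c"] * 30}
        )
        ref = pg.welch_anova(data=df, dv="y", between="g")
        assert f == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)

    def test_insufficient_data_raises(self):
        with pytest.raises(ValueError):
            route_and_test({"a": np.array([1.0, 2.0]), "b": np.array([1.0, 2.0, 3.0])})

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 10.0))
    def test_mann_whitney_invariant_under_monotone_transform(self, seed, scale):
        rng = np.random.default_rng(seed)
        g1 = rng.normal(0, 1, 15)
        g2 = rng.normal(0.5, 1, 15)
        _, u1, p1, _ = route_and_test({"a": g1, "b": g2}, force_route="mann_whitney")
        f = lambda x: np.exp(scale * x)  # strictly increasing
        _, u2, p2, _ = route_and_test({"a": f(g1), "b": f(g2)}, force_route="mann_whitney")
        assert u1 == u2
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestBonferroni:
    def test_textbook_cases(self):
        adj, sig = bonferroni(np.array([0.01]), alpha=0.05)
        assert adj[0] == 0.01 and sig[0]
        adj, sig = bonferroni(np.array([0.01] + [0.5] * 5), alpha=0.05)
        assert adj[0] == pytest.approx(0.06) and not sig[0]
        adj, sig = bonferroni(np.array([0.001] + [0.5] * 11), alpha=0.05)
        assert adj[0] == pytest.approx(0.012) and sig[0]

    def test_adding_tests_never_creates_significance(self):
        p = np.array([0.02, 0.03, 0.2])
        adj_small, sig_small = bonferroni(p, 0.05)
        adj_large, sig_large = bonferroni(np.concatenate([p, [0.9, 0.9]]), 0.05)
        assert not (sig_large[:3] & ~sig_small).any()
        assert (adj_large[:3] >= adj_small).all()

    def test_out_of_range_p_raises(self):
        with pytest.raises(ValueError):
            bonferroni(np.array([1.5]))


class TestGroupComparisons:
    def _cohort(self, seed=0):
        # positive baseline so the percent difference has a stable reference
        effects = {g: np.full(38, 5.0) for g in ("HC", "MDD", "SSD")}
        effects["MDD"] = effects["MDD"].copy()
        effects["MDD"][6] = 5.0 - 0.8  # ppm shifted down in MDD
        return synth_feature_table(15, effects, seed=seed)

    def test_percent_difference_recovers_planted_effect_sign(self):
        table = self._cohort()
        out = compare_groups(table, ["ppm"], pairs=[("MDD", "HC")])
        row = out.iloc[0]
        assert row["pair"] == "MDD-HC"
        assert row["mean_difference_pct"] < 0

    def test_unit_of_analysis_is_participant(self):
        table = self._cohort()
        pm = participant_means(table, ["ppm"])
        assert len(pm) == 45
        out_part = compare_groups(table, ["ppm"], pairs=[("MDD", "HC")])
        out_samp = compare_groups(table, ["ppm"], pairs=[("MDD", "HC")], per_sample=True)
        assert out_part.iloc[0]["statistic"] != out_samp.iloc[0]["statistic"]

    def test_family_correction_covers_whole_table(self):
        table = self._cohort()
        out = compare_groups(table, ["ppm", "f0_sd"], pairs=[("MDD", "HC"), ("SSD", "HC")])
        m = len(out)
        np.testing.assert_allclose(
            out["p_adjusted"], np.minimum(1.0, out["p_raw"] * m), atol=1e-12
        )


class TestSymptomCorrelations:
    def test_exact_linear_feature_has_unit_correlation(self):
        table = synth_feature_table(12, {"MDD": np.zeros(38)}, seed=3)
        scores = synth_symptom_scores(table, seed=3)
        table = table.join(scores, on="participant_id")
        table["ppm"] = 2.0 * table["HAMD"] + 1.0
        out = correlate_symptoms(table, ["ppm"], scales=["HAMD"], groups=("MDD",))
        assert out.iloc[0]["r"] == pytest.approx(1.0)

    def test_planted_correlation_is_recovered_within_sampling_band(self):
        rs = []
        for seed in range(8):
            table = synth_feature_table(20, {"SSD": np.zeros(38)}, seed=seed)
            scores = synth_symptom_scores(
                table, {("HAMD", "SSD"): ("lhr_sd", 0.5)}, seed=seed
            )
            table = table.join(scores, on="participant_id")
            out = correlate_symptoms(table, ["lhr_sd"], scales=["HAMD"], groups=("SSD",))
            rs.append(out.iloc[0]["r"])
        assert np.mean(rs) == pytest.approx(0.5, abs=0.2)

    def test_null_rejection_rate_matches_alpha(self):
        # |r| >= 0.444 is the two-sided 5% critical value at n = 20
        rng = np.random.default_rng(0)
        n, sims = 20, 2000
        x = rng.standard_normal((sims, n))
        y = rng.standard_normal((sims, n))
        xz = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        yz = (y - y.mean(1, keepdims=True)) / y.std(1, keepdims=True)
        r = (xz * yz).mean(axis=1)
        assert abs(np.mean(r) ) < 0.01
        assert np.mean(np.abs(r) >= 0.444) == pytest.approx(0.05, abs=0.015)

    def test_zero_variance_scale_yields_no_row(self):
        table = synth_feature_table(8, {"MDD": np.zeros(38)}, seed=1)
        table["HAMD"] = 5.0
        out = correlate_symptoms(table, ["ppm"], scales=["HAMD"], groups=("MDD",))
        assert out.empty
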