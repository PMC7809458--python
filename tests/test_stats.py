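"""Inter-layer statistics: ANOVA, Levene, Tukey, effect sizes, correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from paleoseason.seasonal import SeasonalEstimate
from paleoseason.stats import (
    anova_oneway,
    cohens_d,
    group_summary,
    layer_report,
    levene_test,
    normality_check,
    season_collagen_correlation,
    tukey_hsd,
)


def make_estimate(layer, winter=None, summer=None, tooth="T"):
    mean = None if winter is None or summer is None else (summer + winter) / 2
    return SeasonalEstimate(
        tooth_id=tooth,
        layer_id=layer,
        summer_peak=summer,
        winter_trough=winter,
        mean_annual=mean,
        seasonality=None if mean is None else summer - winter,
        completeness="both_extremes"
        if winter is not None and summer is not None
        else ("trough_only" if winter is not None else "peak_only"),
    )


GROUPS3 = {
    "2": np.array([24.0, 26.0, 25.0, 27.0, 23.0]),
    "5A": np.array([30.0, 31.0, 29.0, 32.0]),
    "5B": np.array([28.0, 27.5, 29.5]),
}


class TestGroupSummary:
    def test_hand_arithmetic(self):
        ests = [make_estimate("2", winter=-6.0, tooth="a"), make_estimate("2", winter=-8.0, tooth="b")]
        out = group_summary(ests, "winter")
        assert out.loc[0, "mean"] == pytest.approx(-7.0)
        assert out.loc[0, "sd"] == pytest.approx(np.sqrt(2.0))
        assert out.loc[0, "n"] == 2

    def test_partial_series_contribute_only_their_season(self):
        ests = [
            make_estimate("2", winter=-6.0, summer=-3.0, tooth="a"),
            make_estimate("2", winter=-8.0, tooth="b"),  # trough only
        ]
        assert group_summary(ests, "winter").loc[0, "n"] == 2
        assert group_summary(ests, "summer").loc[0, "n"] == 1

    def test_layers_in_stratigraphic_order(self):
        ests = [
            make_estimate("5B", winter=-6.0),
            make_estimate("2", winter=-7.0),
            make_estimate("5A", winter=-6.5),
        ]
        assert list(group_summary(ests, "winter")["layer_id"]) == ["2", "5A", "5B"]

    def test_absent_season_errors(self):
        with pytest.raises(ValueError):
            group_summary([make_estimate("2", winter=-6.0)], "summer")


class TestAnova:
    def test_identical_groups(self):
        F, p = anova_oneway({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        assert F == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_sums_of_squares_oracle(self):
        F, _ = anova_oneway(GROUPS3)
        allv = np.concatenate(list(GROUPS3.values()))
        grand = allv.mean()
        ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in GROUPS3.values())
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in GROUPS3.values())
        df_b = len(GROUPS3) - 1
        df_w = allv.size - len(GROUPS3)
        assert F == pytest.approx((ss_between / df_b) / (ss_within / df_w), abs=1e-10)

    def test_two_groups_equal_t_squared(self):
        a = np.array([24.0, 26.0, 25.0, 27.0, 23.0])
        b = np.array([30.0, 31.0, 29.0, 32.0])
        F, p_f = anova_oneway({"a": a, "b": b})
        t, p_t = sps.ttest_ind(a, b, equal_var=True)
        assert F == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway({"a": [1.0], "b": [1.0, 2.0]})


class TestLevene:
    def test_gross_variance_difference(self):
        groups = {"a": [0.0, 0.2, -0.2, 0.1, -0.1, 0.05], "b": [0.0, 10.0, -10.0, 5.0, -5.0, 8.0]}
        assert levene_test(groups) < 0.05

    def test_null_p_uniform(self):
        """Under equal variances the Levene p-value is ~Uniform(0,1).

        Group sizes are large enough (n=40) for the test's F approximation
        to be accurate; at very small n the approximation itself deviates.
        """
        rng = np.random.default_rng(12)
        ps = [
            levene_test({"a": rng.normal(0, 1, 40), "b": rng.normal(2, 1, 40), "c": rng.normal(-1, 1, 40)})
            for _ in range(500)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_median_center_option(self):
        groups = {"a": [1.0, 2, 3, 9], "b": [1.0, 2, 3, 4]}
        assert levene_test(groups, center="median") != levene_test(groups, center="mean")


class TestTukey:
    def test_identical_groups_p_one(self):
        out = tukey_hsd({"a": [1.0, 2, 3], "b": [1.0, 2, 3], "c": [1.0, 2, 3]})
        assert np.allclose(out["p_adj"], 1.0, atol=1e-9)

    def test_matches_statsmodels_oracle(self):
        """Cross-check adjusted p against statsmodels' independent Tukey HSD."""
        from itertools import combinations

        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        values = np.concatenate(list(GROUPS3.values()))
        labels = np.concatenate([[k] * len(v) for k, v in GROUPS3.items()])
        sm = pairwise_tukeyhsd(values, labels)
        sm_p = {
            frozenset(pair): p
            for pair, p in zip(combinations(sm.groupsunique, 2), sm.pvalues)
        }
        ours = tukey_hsd(GROUPS3)
        for _, row in ours.iterrows():
            key = frozenset((row.group_a, row.group_b))
            assert row.p_adj == pytest.approx(sm_p[key], abs=5e-3)

    def test_adjusted_p_not_below_pairwise_t(self):
        rng = np.random.default_rng(21)
        groups = {k: rng.normal(m, 1.0, 8) for k, m in (("a", 0.0), ("b", 0.6), ("c", 1.2))}
        out = tukey_hsd(groups)
        for _, row in out.iterrows():
            _, p_t = sps.ttest_ind(groups[row.group_a], groups[row.group_b], equal_var=True)
            assert row.p_adj >= p_t - 1e-9

    def test_unbalanced_groups_supported(self):
        out = tukey_hsd(GROUPS3)
        assert len(out) == 3
        assert ((out["p_adj"] >= 0) & (out["p_adj"] <= 1)).all()


class TestCohensD:
    def test_hand_computation(self):
        assert cohens_d([1.0, 2, 3], [3.0, 4, 5]) == pytest.approx(-2.0)

    def test_identical_groups_zero(self):
        assert cohens_d([1.0, 2, 3], [1.0, 2, 3]) == 0.0

    def test_zero_pooled_sd_with_different_means_undefined(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [2.0, 2.0])

    @settings(max_examples=40, derandomize=True)
    @given(
        shift=st.floats(-50, 50),
        scale=st.floats(0.1, 10.0),
        seed=st.integers(0, 1000),
    )
    def test_antisymmetry_shift_and_scale_invariance(self, shift, scale, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 8)
        d = cohens_d(a, b)
        assert cohens_d(b, a) == pytest.approx(-d, rel=1e-9)
        assert cohens_d(a + shift, b + shift) == pytest.approx(d, rel=1e-6, abs=1e-9)
        assert cohens_d(a * scale, b * scale) == pytest.approx(d, rel=1e-6, abs=1e-9)


class TestCorrelation:
    def test_perfectly_collinear(self):
        ests = [
            make_estimate("2", winter=-8.0),
            make_estimate("5A", winter=-7.0),
            make_estimate("5B", winter=-6.0),
        ]
        coll = pd.DataFrame(
            {"layer_id": ["2", "5A", "5B"], "d13C": [-19.0, -20.0, -21.0]}
        )
        out = season_collagen_correlation(ests, coll, pairing="per_layer")
        assert out["r"] == pytest.approx(-1.0)
        assert out["R2"] == pytest.approx(1.0)

    def test_definition_oracle(self):
        ests = [make_estimate(l, winter=w) for l, w in (("1", -9.0), ("2", -8.0), ("3", -7.5), ("4", -6.0), ("5A", -5.0))]
        coll = pd.DataFrame(
            {"layer_id": ["1", "2", "3", "4", "5A"], "d13C": [-19.1, -19.6, -20.4, -20.2, -21.0]}
        )
        out = season_collagen_correlation(ests, coll, pairing="per_layer")
        x = np.array([-9.0, -8.0, -7.5, -6.0, -5.0])
        y = np.array([-19.1, -19.6, -20.4, -20.2, -21.0])
        r_hand = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert out["r"] == pytest.approx(r_hand, abs=1e-12)
        assert out["R2"] == pytest.approx(r_hand**2, abs=1e-12)

    def test_per_specimen_pairing_n(self):
        ests = [
            make_estimate("2", winter=-8.0),
            make_estimate("5A", winter=-7.0),
            make_estimate("5B", winter=-6.5),
        ]
        coll = pd.DataFrame(
            {"layer_id": ["2", "2", "5A", "5A", "5B", "1"], "d13C": [-19, -19.2, -20, -20.1, -20.3, -18.0]}
        )
        out = season_collagen_correlation(ests, coll, pairing="per_specimen")
        assert out["n"] == 5  # layer 1 has no winter estimate

    def test_too_few_pairs(self):
        ests = [make_estimate("2", winter=-8.0), make_estimate("5A", winter=-7.0)]
        coll = pd.DataFrame({"layer_id": ["2", "5A"], "d13C": [-19.0, -20.0]})
        with pytest.raises(ValueError):
            season_collagen_correlation(ests, coll, pairing="per_layer")


class TestNormality:
    def test_normal_sample_rarely_flagged(self):
        hits = 0
        for rep in range(200):
            rng = np.random.default_rng(rep)
            if normality_check(rng.standard_normal(50))["shapiro_p"] > 0.05:
                hits += 1
        assert hits >= 180

    def test_gross_non_normality(self):
        assert normality_check([1.0, 1.0, 1.0, 1.0, 100.0])["shapiro_p"] < 0.01

    def test_quantile_table_length(self):
        out = normality_check(np.arange(17.0))
        assert len(out["qq"]) == 17


def test_layer_report_bundles_everything():
    rng = np.random.default_rng(2)
    ests = []
    for layer, mu in (("2", -8.0), ("5A", -6.5), ("5B", -6.8)):
        for i in range(4):
            w = rng.normal(mu, 0.3)
            ests.append(make_estimate(layer, winter=w, summer=w + 4.0, tooth=f"{layer}-{i}"))
    rep = layer_report(ests, "winter")
    assert set(rep.summary["layer_id"]) == {"2", "5A", "5B"}
    assert rep.anova_p < 0.05
    assert len(rep.tukey) == 3
    d = rep.effect_sizes.query("group_a == '2' and group_b == '5A'").cohens_d.iloc[0]
    assert d < -2  # older layer has markedly lower winter values
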