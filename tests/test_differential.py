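"""Two-group fits, empirical-Bayes moderation, BH adjustment, volcano rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sulfomics.differential import (
    ContrastDesign,
    bh_adjust,
    differential_analysis,
    eb_moderate,
    fit_feature_models,
    moderated_t_and_p,
    volcano_classify,
)
from sulfomics.synthetic_study import MarkerSpec, generate_study

from test_preprocess import toy_table


def _design(n1=3, n2=3):
    return ContrastDesign(
        baseline=tuple(f"S{i}" for i in range(1, n1 + 1)),
        post=tuple(f"S{i}" for i in range(n1 + 1, n1 + n2 + 1)),
    )


class TestFitFeatureModels:
    def test_identical_groups_zero_fc(self):
        areas = np.tile([100.0, 200.0, 400.0], (3, 2))
        t = toy_table(areas=areas, n_feat=3, n_samp=6)
        fits = fit_feature_models(t, _design())
        np.testing.assert_allclose(fits["log2fc"], 0, atol=1e-12)

    def test_doubling_post_shifts_fc_by_one(self):
        rng = np.random.default_rng(0)
        areas = rng.uniform(10, 100, size=(4, 6))
        t = toy_table(areas=areas, n_feat=4, n_samp=6)
        base = fit_feature_models(t, _design())["log2fc"]
        areas2 = areas.copy()
        areas2[:, 3:] *= 2
        t2 = toy_table(areas=areas2, n_feat=4, n_samp=6)
        shifted = fit_feature_models(t2, _design())["log2fc"]
        np.testing.assert_allclose(shifted - base, 1.0, atol=1e-12)

    def test_toy_matches_hand_computed_pooled_t_inputs(self):
        a = np.array([8.0, 16.0, 32.0])  # log2: 3,4,5
        b = np.array([64.0, 128.0, 256.0])  # log2: 6,7,8
        areas = np.concatenate([a, b])[np.newaxis, :].repeat(2, axis=0)
        t = toy_table(areas=areas, n_feat=2, n_samp=6)
        fits = fit_feature_models(t, _design())
        assert fits["log2fc"].iloc[0] == pytest.approx(3.0)
        assert fits["s2"].iloc[0] == pytest.approx(1.0)  # pooled var of {3,4,5},{6,7,8}
        assert fits["df"].iloc[0] == 4

    def test_small_condition_rejected(self):
        with pytest.raises(ValueError):
            ContrastDesign(baseline=("S1",), post=("S2", "S3"))


class TestEbModerate:
    def test_equal_variances_collapse_to_common_value(self):
        prior, post = eb_moderate(np.full(100, 0.3), 10)
        assert np.isinf(prior.d0)
        np.testing.assert_allclose(post, 0.3, rtol=1e-12)

    def test_zero_prior_df_keeps_ordinary_variances(self):
        s2 = np.array([0.1, 0.5, 2.0])
        # d0 = 0 means no shrinkage: posterior formula reduces to s2
        post = (0.0 * 1.0 + 10 * s2) / (0.0 + 10)
        np.testing.assert_allclose(post, s2)

    def test_simulated_prior_recovered_within_10pct(self):
        rng = np.random.default_rng(3)
        d0, s0_sq, df, n = 4.0, 0.05, 10, 5000
        sigma2 = d0 * s0_sq / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(df, n) / df
        prior, post = eb_moderate(s2, df)
        assert prior.d0 == pytest.approx(d0, rel=0.10)
        assert prior.s0_sq == pytest.approx(s0_sq, rel=0.10)
        # shrinkage: posterior lies between the observation and the prior
        between = ((post >= np.minimum(s2, prior.s0_sq)) & (post <= np.maximum(s2, prior.s0_sq)))
        assert between.all()

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            eb_moderate(np.zeros(20), 4)


class TestModeratedT:
    def test_zero_fc_gives_p_one(self):
        t, p = moderated_t_and_p(np.array([0.0]), np.array([0.5]), 4, 3.0, 3, 3)
        assert t[0] == 0.0
        assert p[0] == pytest.approx(1.0)

    def test_d0_zero_reduces_to_classical_pooled_t(self):
        rng = np.random.default_rng(4)
        a = rng.normal(5, 1, 6)
        b = rng.normal(6, 1, 5)
        s2 = (a.var(ddof=1) * 5 + b.var(ddof=1) * 4) / 9
        fc = b.mean() - a.mean()
        t, p = moderated_t_and_p(np.array([fc]), np.array([s2]), 9, 0.0, 6, 5)
        ref = stats.ttest_ind(b, a, equal_var=True)
        assert t[0] == pytest.approx(ref.statistic)
        assert p[0] == pytest.approx(ref.pvalue)

    def test_large_d0_approaches_z_test(self):
        fc, s0_sq = np.array([0.8]), 0.25
        t_inf, p_inf = moderated_t_and_p(fc, np.array([s0_sq]), 4, np.inf, 5, 5)
        z = fc[0] / np.sqrt(s0_sq * (1 / 5 + 1 / 5))
        assert p_inf[0] == pytest.approx(2 * stats.norm.sf(abs(z)))
        _, p_big = moderated_t_and_p(fc, np.array([s0_sq]), 4, 1e7, 5, 5)
        assert p_big[0] == pytest.approx(p_inf[0], rel=1e-4)


def brute_force_bh(p):
    """O(n^2) step-up oracle: adj_i = min over thresholds >= p_i of n*p_j/rank_j."""
    p = np.asarray(p, dtype=float)
    n = p.size
    out = np.empty(n)
    for i in range(n):
        candidates = []
        for j in range(n):
            if p[j] >= p[i]:
                rank = np.sum(p <= p[j])
                candidates.append(n * p[j] / rank)
        out[i] = min(1.0, min(candidates))
    return out


class TestBhAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.042])), [0.042])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.full(7, 0.2)), 0.2)

    def test_matches_bruteforce_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        for _ in range(25):
            p = rng.uniform(size=rng.integers(1, 40))
            mine = bh_adjust(p)
            np.testing.assert_allclose(mine, brute_force_bh(p), atol=1e-12)
            np.testing.assert_allclose(
                mine, multipletests(p, method="fdr_bh")[1], atol=1e-12
            )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=50)
        assert (bh_adjust(p) >= p - 1e-15).all()


class TestVolcanoClassify:
    @pytest.mark.parametrize(
        "adj_p, fc, expected_class, expected_dir",
        [
            (0.5, 5.0, "non-significant", "up"),
            (0.01, 2.0, "mid-significant", "up"),
            (0.01, -3.5, "significant", "down"),
            (0.1, 3.0, "significant", "up"),  # both boundaries inclusive
            (0.1, -2.999, "mid-significant", "down"),
            (0.2, 0.0, "non-significant", "none"),
        ],
    )
    def test_rules(self, adj_p, fc, expected_class, expected_dir):
        classes, direction = volcano_classify(np.array([adj_p]), np.array([fc]))
        assert classes[0] == expected_class
        assert direction[0] == expected_dir

    @given(
        st.floats(min_value=1e-12, max_value=1.0),
        st.floats(min_value=-20, max_value=20),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_partition_exhaustive_and_exclusive(self, adj_p, fc):
        classes, _ = volcano_classify(np.array([adj_p]), np.array([fc]))
        assert classes[0] in ("non-significant", "mid-significant", "significant")
        # the three rules are mutually exclusive re-derivations
        n_matched = sum(
            [
                adj_p > 0.1,
                adj_p <= 0.1 and abs(fc) < 3,
                adj_p <= 0.1 and abs(fc) >= 3,
            ]
        )
        assert n_matched == 1


class TestTypeOneControl:
    def test_null_group_contrast_controls_fdr(self):
        # singleton replicates make every sample an independent biological
        # draw, so the two-group test is calibrated; over 20 null studies
        # the fraction of adj p < 0.1 stays near/below 0.1
        from sulfomics.synthetic_study import StudyDesign

        fracs = []
        design = StudyDesign(
            horses={"oral_1": "oral", "im_1": "IM"}, replicates=1, qc_horse="im_1"
        )
        for r in range(20):
            ds = generate_study(
                design=design, markers=[], n_background=60, seed=400 + r,
                background_effect_fraction=0.0, missing_rate=0.0,
            )
            from sulfomics.preprocess import impute_missing, lowess_normalize

            table = impute_missing(lowess_normalize(ds.table)[0])
            s = table.samples
            post = s.index[(s["role"] == "sample") & (s["time_h"] > 0)]
            oral = tuple(p for p in post if s.loc[p, "group"] == "oral")
            im = tuple(p for p in post if s.loc[p, "group"] == "IM")
            res = differential_analysis(table, ContrastDesign(oral, im))
            fracs.append((res["adj_p"] < 0.1).mean())
        mean_frac = np.mean(fracs)
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert mean_frac <= 0.1 + 3 * se


def test_differential_analysis_on_study_is_consistent(normalized):
    table, _ = normalized
    s = table.samples
    horse = "im_1"
    is_horse = s.index.str.startswith(horse) & (s["role"] == "sample")
    base = tuple(s.index[is_horse & (s["time_h"] == 0)])
    post = tuple(s.index[is_horse & (s["time_h"] > 0)])
    res = differential_analysis(table, ContrastDesign(base, post))
    counts = res["volcano_class"].value_counts()
    assert counts.sum() == table.n_features
    assert (res["adj_p"] >= res["p"] - 1e-15).all()
    # planted responders should be enriched among the passing tiers
    assert (res["volcano_class"] != "non-significant").any()
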