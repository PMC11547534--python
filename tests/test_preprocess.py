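"""Feature-table I/O, filtering, imputation, LOWESS normalization, PCA."""

import numpy as np
import pandas as pd
import pytest

from sulfomics.preprocess import (
    FeatureTable,
    FilterConfig,
    filter_features,
    impute_missing,
    lowess_normalize,
    pca_scores,
    read_feature_table,
    write_feature_table,
)


def toy_table(areas=None, n_feat=3, n_samp=6, qc_every=None):
    """Small hand-wired table; samples alternate roles if qc_every set."""
    fids = [f"F{i}" for i in range(1, n_feat + 1)]
    sids = [f"S{i}" for i in range(1, n_samp + 1)]
    features = pd.DataFrame(
        {"mz": np.linspace(200, 400, n_feat), "rt": np.linspace(1, 20, n_feat)},
        index=pd.Index(fids, name="feature_id"),
    )
    roles = ["sample"] * n_samp
    if qc_every:
        roles = ["QC" if (i % qc_every == 0) else "sample" for i in range(n_samp)]
    samples = pd.DataFrame(
        {
            "role": roles,
            "group": ["oral"] * n_samp,
            "time_h": list(range(n_samp)),
            "replicate": [1] * n_samp,
            "injection_order": list(range(1, n_samp + 1)),
        },
        index=pd.Index(sids, name="sample_id"),
    )
    if areas is None:
        areas = np.arange(1, n_feat * n_samp + 1, dtype=float).reshape(n_feat, n_samp) * 10
    return FeatureTable(features, samples, pd.DataFrame(areas, index=features.index, columns=samples.index))


class TestTableIO:
    def test_round_trip_is_lossless(self, tmp_path, study):
        path = tmp_path / "table.csv"
        write_feature_table(study.table, path)
        back = read_feature_table(path)
        pd.testing.assert_frame_equal(back.features, study.table.features[["mz", "rt"]])
        pd.testing.assert_frame_equal(
            back.samples, study.table.samples[back.samples.columns], check_dtype=False
        )
        pd.testing.assert_frame_equal(back.areas, study.table.areas)

    def test_blank_cells_become_missing(self, tmp_path):
        t = toy_table(areas=np.array([[1.0, np.nan, 3.0], [4.0, 5.0, 6.0]]), n_feat=2, n_samp=3)
        path = tmp_path / "t.csv"
        write_feature_table(t, path)
        assert ",," in path.read_text().splitlines()[-2]  # blank cell written
        back = read_feature_table(path)
        assert np.isnan(back.areas.iloc[0, 1])

    def test_metadata_rows_carry_roles(self, tmp_path):
        t = toy_table(qc_every=3)
        path = tmp_path / "t.csv"
        write_feature_table(t, path)
        lines = path.read_text().splitlines()
        assert lines[1].startswith("role,,")
        assert "QC" in lines[1]

    def test_duplicate_sample_id_rejected(self, tmp_path):
        t = toy_table()
        path = tmp_path / "t.csv"
        write_feature_table(t, path)
        text = path.read_text().replace("S2", "S1", 1)
        path.write_text(text)
        with pytest.raises(ValueError, match="duplicate sample"):
            read_feature_table(path)

    def test_provenance_comments_skipped(self, tmp_path):
        t = toy_table()
        path = tmp_path / "t.csv"
        write_feature_table(t, path, header_lines=["tool x", "seed=1"])
        assert path.read_text().startswith("# tool x\n# seed=1\n")
        back = read_feature_table(path)
        pd.testing.assert_frame_equal(back.areas, t.areas)

    def test_container_invariants(self):
        with pytest.raises(ValueError, match="injection orders"):
            t = toy_table()
            s = t.samples.copy()
            s["injection_order"] = 1
            FeatureTable(t.features, s, t.areas)
        with pytest.raises(ValueError, match="negative"):
            t = toy_table()
            a = t.areas.copy()
            a.iloc[0, 0] = -5.0
            FeatureTable(t.features, t.samples, a)


class TestFilterFeatures:
    def test_zero_fill_threshold_is_identity(self):
        t = toy_table()
        out = filter_features(t, FilterConfig(min_fill=0.0))
        pd.testing.assert_frame_equal(out.areas, t.areas)

    def test_full_fill_drops_feature_missing_once(self):
        areas = np.ones((3, 6)) * 100
        areas[1, 2] = np.nan
        t = toy_table(areas=areas)
        out = filter_features(t, FilterConfig(min_fill=1.0))
        assert list(out.features.index) == ["F1", "F3"]

    def test_survivor_count_matches_enumeration(self):
        rng = np.random.default_rng(0)
        areas = rng.uniform(10, 100, size=(10, 8))
        mask = rng.random((10, 8)) < 0.3
        areas[mask] = np.nan
        t = toy_table(areas=areas, n_feat=10, n_samp=8)
        thresh = 0.75
        expected = sum(1 for i in range(10) if (~np.isnan(areas[i])).mean() >= thresh)
        out = filter_features(t, FilterConfig(min_fill=thresh))
        assert out.n_features == expected

    def test_invalid_fill_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(min_fill=1.5)


class TestImputeMissing:
    def test_twenty_percent_of_minimum(self):
        areas = np.array([[100.0, np.nan, 500.0], [np.nan, 40.0, 80.0]])
        t = toy_table(areas=areas, n_feat=2, n_samp=3)
        out = impute_missing(t)
        assert out.areas.iloc[0, 1] == pytest.approx(20.0)  # 0.2 * 100
        assert out.areas.iloc[1, 0] == pytest.approx(8.0)  # features independent

    def test_no_missing_is_identity(self):
        t = toy_table()
        pd.testing.assert_frame_equal(impute_missing(t).areas, t.areas)

    def test_all_missing_feature_rejected(self):
        areas = np.array([[np.nan, np.nan, np.nan], [1.0, 2.0, 3.0]])
        t = toy_table(areas=areas, n_feat=2, n_samp=3)
        with pytest.raises(ValueError, match="no observed"):
            impute_missing(t)

    def test_impute_and_filter_commute(self):
        # filters that don't depend on imputed cells: same survivors either way
        rng = np.random.default_rng(1)
        areas = rng.uniform(10, 100, size=(8, 6))
        areas[rng.random((8, 6)) < 0.2] = np.nan
        areas[(np.isnan(areas).all(axis=1))] = 50.0  # keep every feature imputable
        t = toy_table(areas=areas, n_feat=8, n_samp=6)
        cfg = FilterConfig(min_fill=0.5)
        a = impute_missing(filter_features(t, cfg))
        kept = filter_features(t, cfg).features.index
        b = impute_missing(t).subset_features(kept)
        pd.testing.assert_frame_equal(a.areas, b.areas)


class TestLowessNormalize:
    def _drift_table(self, drift=True, n_feat=5, n_samp=40, seed=2):
        rng = np.random.default_rng(seed)
        base = rng.uniform(1e4, 1e5, size=n_feat)
        areas = np.outer(base, np.ones(n_samp))
        areas *= np.exp(rng.normal(0, 0.05, size=(n_feat, n_samp)))
        if drift:
            mult = np.linspace(0.8, 1.2, n_samp)
            areas = areas * mult
        return toy_table(areas=areas, n_feat=n_feat, n_samp=n_samp, qc_every=5)

    def test_drift_free_constant_feature_unchanged(self):
        areas = np.full((3, 40), 1234.5)
        t = toy_table(areas=areas, n_feat=3, n_samp=40, qc_every=5)
        out, report = lowess_normalize(t)
        np.testing.assert_allclose(out.areas.to_numpy(), areas, rtol=1e-9)

    def test_linear_drift_reduces_qc_cv(self):
        t = self._drift_table()
        out, report = lowess_normalize(t)
        assert (report["qc_cv_after"] < report["qc_cv_before"]).all()

    def test_residual_qc_trend_removed(self):
        t = self._drift_table(seed=3)
        out, _ = lowess_normalize(t)
        qc = t.sample_ids(role="QC")
        io = t.samples.loc[qc, "injection_order"].to_numpy(dtype=float)
        for fid in t.features.index:
            before = np.polyfit(io, t.areas.loc[fid, qc] / t.areas.loc[fid, qc].mean(), 1)[0]
            after = np.polyfit(io, out.areas.loc[fid, qc] / out.areas.loc[fid, qc].mean(), 1)[0]
            assert abs(after) < 0.1 * abs(before)

    def test_too_few_qcs_rejected_with_advice(self):
        t = toy_table()  # no QC samples at all
        with pytest.raises(ValueError, match="pass-through"):
            lowess_normalize(t)

    def test_correction_is_positive_rescaling(self):
        # each cell is multiplied by a positive factor, so ordering of
        # values sharing an injection position can never change
        t = self._drift_table(seed=4)
        out, _ = lowess_normalize(t)
        factor = out.areas.to_numpy() / t.areas.to_numpy()
        assert (factor > 0).all()


class TestPcaScores:
    def test_duplicated_samples_identical_scores(self):
        rng = np.random.default_rng(5)
        areas = rng.uniform(10, 1000, size=(6, 4))
        areas[:, 3] = areas[:, 2]
        t = toy_table(areas=areas, n_feat=6, n_samp=4)
        scores, _ = pca_scores(t, k=2)
        np.testing.assert_allclose(scores.iloc[2], scores.iloc[3], atol=1e-9)

    def test_two_cluster_toy_separated_on_pc1(self):
        lo, hi = 10.0, 10000.0
        areas = np.column_stack([[lo] * 5] * 3 + [[hi] * 5] * 3)
        rng = np.random.default_rng(6)
        areas = areas * np.exp(rng.normal(0, 0.01, size=areas.shape))
        t = toy_table(areas=areas, n_feat=5, n_samp=6)
        scores, ratios = pca_scores(t, k=2)
        pc1 = scores["PC1"].to_numpy()
        assert (pc1[:3].max() < pc1[3:].min()) or (pc1[3:].max() < pc1[:3].min())
        assert ratios[0] >= ratios[1]
        assert ratios.sum() <= 1.0 + 1e-9

    def test_constant_matrix_rejected(self):
        t = toy_table(areas=np.full((3, 6), 7.0))
        with pytest.raises(ValueError, match="degenerate"):
            pca_scores(t)


class TestQcGeometryOnStudy:
    def _mean_pairwise(self, pts):
        from scipy.spatial.distance import pdist

        return pdist(pts).mean()

    def test_qc_cluster_tighter_than_study_groups(self, study, normalized):
        table, _ = normalized
        scores, _ = pca_scores(table, k=2)
        qc = scores.loc[study.table.sample_ids(role="QC")]
        d_qc = self._mean_pairwise(qc.to_numpy())
        d_groups = []
        for g in ("oral", "IM"):
            ids = study.table.sample_ids(role="sample", group=g)
            d_groups.append(self._mean_pairwise(scores.loc[ids].to_numpy()))
        assert d_qc < min(d_groups)

    def test_normalization_shrinks_qc_spread(self, study, normalized):
        from sulfomics.preprocess import impute_missing

        table, _ = normalized
        raw = impute_missing(study.table)
        qc_ids = study.table.sample_ids(role="QC")
        before, _ = pca_scores(raw, k=2)
        after, _ = pca_scores(table, k=2)
        assert self._mean_pairwise(after.loc[qc_ids].to_numpy()) < self._mean_pairwise(
            before.loc[qc_ids].to_numpy()
        )
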