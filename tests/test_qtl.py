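"""Feature filtering, rank inverse-normal transform, UMAP covariates, cis scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ctrich import qtl as q
from ctrich import simulate as sim
from ctrich import stats as st


def _matrix(rows, samples=None):
    samples = samples or [f"S{i}" for i in range(len(next(iter(rows.values()))))]
    return pd.DataFrame(rows, index=samples).T


class TestFilterFeatures:
    def test_tpm_rule_drops_gene_low_in_more_than_a_third(self):
        mat = _matrix({
            "G_low": [0, 0, 0, 5, 5, 5],      # low in 3/6 > 1/3 -> dropped
            "G_edge": [0, 0, 5, 5, 5, 5],     # low in 2/6 = 1/3 exactly -> kept
            "G_high": [2, 3, 4, 5, 6, 7],
        })
        kept, audit = q.filter_features(mat, "TPM")
        assert set(kept.index) == {"G_edge", "G_high"}
        dropped = audit[(audit.type == "feature") & (~audit.kept)]
        assert list(dropped["item"]) == ["G_low"]

    def test_ctss_read_depth_and_presence_rules(self):
        mat = _matrix({
            # >5 reads in 12 (>10) samples, present 30/30
            "keep": [6] * 12 + [1] * 18,
            # >5 reads in only 10 samples (rule is strictly >10)
            "depth_fail": [6] * 10 + [1] * 20,
            # deep enough but detected in 26/30 = 87% < 90%
            "presence_fail": [50] * 26 + [0] * 4,
        })
        kept, audit = q.filter_features(mat, "CTSS-count")
        assert set(kept.index) == {"keep"}
        reasons = audit.set_index("item")["reason"]
        assert "samples" in reasons["depth_fail"]
        assert "detected" in reasons["presence_fail"]

    def test_sample_aged_fifteen_dropped_before_feature_filters(self):
        mat = _matrix({"F": [10] * 12})
        ages = pd.Series([15.0] + [40.0] * 11, index=mat.columns)
        kept, audit = q.filter_features(mat, "CTSS-count", ages=ages)
        assert mat.columns[0] not in kept.columns
        sample_rows = audit[audit.type == "sample"]
        assert list(sample_rows["item"]) == [mat.columns[0]]

    def test_missingness_and_low_variance_options(self):
        rng = np.random.default_rng(2)
        mat = _matrix({
            "sparse": [0.0] * 8 + [2.0] * 4,           # detected in 4/12 < 0.5
            "flat": [1.5 + 1e-6 * i for i in range(12)],
            "varied": list(rng.normal(10, 3, 12).clip(1.1)),
        })
        cfg = q.QtlFilterConfig(tpm_fraction=1.0, missingness_threshold=0.5,
                                low_variance_quantile=0.5)
        kept, _ = q.filter_features(mat, "TPM", cfg)
        assert set(kept.index) == {"varied"}

    def test_audit_conserves_every_feature(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.poisson(8, size=(20, 15)),
                           index=[f"f{i}" for i in range(20)])
        kept, audit = q.filter_features(mat, "CTSS-count")
        feat_audit = audit[audit.type == "feature"]
        assert len(feat_audit) == 20
        assert feat_audit["kept"].sum() == len(kept)

    def test_empty_result_is_hard_error(self):
        mat = _matrix({"F": [0.0] * 6})
        with pytest.raises(ValueError, match="all features removed"):
            q.filter_features(mat, "TPM")


class TestQuantileNormalize:
    def test_three_sample_closed_form(self):
        mat = _matrix({"F": [1.0, 2.0, 3.0]})
        out, flags = q.quantile_normalize(mat)
        expected = sps.norm.ppf([1 / 6, 3 / 6, 5 / 6])
        assert np.allclose(out.loc["F"], expected)
        assert flags == []

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        vals = rng.gamma(2.0, 3.0, size=50)
        m1 = _matrix({"F": list(vals)})
        m2 = _matrix({"F": list(np.log1p(vals) ** 3)})
        o1, _ = q.quantile_normalize(m1)
        o2, _ = q.quantile_normalize(m2)
        assert np.allclose(o1.to_numpy(), o2.to_numpy())

    def test_constant_feature_becomes_zeros_and_flagged(self):
        mat = _matrix({"F": [2.0] * 10, "G": list(range(10))})
        with pytest.warns(UserWarning, match="constant"):
            out, flags = q.quantile_normalize(mat)
        assert flags == ["F"]
        assert (out.loc["F"] == 0).all()

    def test_heavy_tailed_feature_normalized_to_gaussian_shape(self):
        rng = np.random.default_rng(13)
        reps, passed = 40, 0
        for _ in range(reps):
            mat = _matrix({"F": list(rng.standard_cauchy(80))})
            out, _ = q.quantile_normalize(mat)
            if sps.shapiro(out.loc["F"]).pvalue > 0.01:
                passed += 1
        assert passed >= 0.95 * reps

    def test_rows_centered_near_zero(self):
        rng = np.random.default_rng(17)
        mat = pd.DataFrame(rng.exponential(5, size=(5, 40)))
        out, _ = q.quantile_normalize(mat)
        assert np.abs(out.mean(axis=1)).max() < 1e-8


class TestUmapCovariates:
    def test_two_planted_clusters_are_separated(self):
        rng = np.random.default_rng(19)
        a = rng.normal(0, 1, size=(30, 25))
        b = rng.normal(6, 1, size=(30, 25))
        mat = pd.DataFrame(np.vstack([a, b]).T,
                           columns=[f"S{i}" for i in range(60)])
        emb = q.umap_covariates(mat, n_components=2, seed=7)
        labels = np.array([0] * 30 + [1] * 30)
        from sklearn.metrics import silhouette_score

        assert silhouette_score(emb.to_numpy(), labels) > 0.5

    def test_fixed_seed_is_deterministic(self):
        rng = np.random.default_rng(23)
        mat = pd.DataFrame(rng.normal(size=(20, 15)))
        e1 = q.umap_covariates(mat, seed=3)
        e2 = q.umap_covariates(mat, seed=3)
        assert np.array_equal(e1.to_numpy(), e2.to_numpy())

    def test_zero_components_is_a_no_op(self):
        mat = pd.DataFrame(np.ones((5, 12)))
        assert q.umap_covariates(mat, n_components=0).empty

    def test_too_few_samples_warns_and_skips(self):
        mat = pd.DataFrame(np.ones((5, 6)))
        with pytest.warns(UserWarning, match="fewer than 10"):
            emb = q.umap_covariates(mat, n_components=2)
        assert emb.empty


@pytest.fixture(scope="module")
def qtl_inputs():
    cfg = sim.SimulationConfig(n_samples=78, seed=61)
    cohort = sim.simulate_cohort(cfg)
    spec = sim.ExpressionSpec(n_features=40, planted_betas={20: ("H4", -0.8)})
    counts, coords = sim.simulate_expression(cohort, spec, np.random.default_rng(63))
    norm, _ = q.quantile_normalize(counts)
    variants = cohort.set_index("sample_id")[["dosage_H4"]]
    variants.columns = ["H4"]
    positions = pd.DataFrame({"variant": ["H4"], "chrom": "chr4", "pos": [sim.REPEAT_POS]})
    covs = cohort.set_index("sample_id")[list(st.DEFAULT_COVARIATES)]
    return cohort, norm, coords, variants, positions, covs


class TestCisScan:
    def test_far_feature_is_not_tested(self, qtl_inputs):
        _, norm, coords, variants, positions, covs = qtl_inputs
        res = q.cis_scan(variants, positions, norm, coords, covs)
        tested = set(res["feature"])
        far = coords[(coords["start"] - sim.REPEAT_POS).abs() > 1_100_000]["feature"]
        assert tested.isdisjoint(set(far))
        near = coords[(coords["start"] - sim.REPEAT_POS).abs() < 900_000]["feature"]
        assert set(near) <= tested

    def test_planted_feature_attains_smallest_fdr(self, qtl_inputs):
        _, norm, coords, variants, positions, covs = qtl_inputs
        res = q.cis_scan(variants, positions, norm, coords, covs)
        assert res.sort_values("FDR").iloc[0]["feature"] == "ctss_0020"

    def test_matches_ols_assoc_exactly_with_zero_covariates(self, qtl_inputs):
        _, norm, coords, variants, positions, _ = qtl_inputs
        res = q.cis_scan(variants, positions, norm, coords, covariates=None)
        feature = "ctss_0020"
        row = res[res.feature == feature].iloc[0]
        ref = st.ols_assoc(norm.loc[feature, variants.index], variants["H4"])
        assert row["beta"] == pytest.approx(ref.beta, abs=1e-10)
        assert row["SE"] == pytest.approx(ref.SE, abs=1e-10)
        assert row["p_nominal"] == pytest.approx(ref.P, abs=1e-10)

    def test_matches_ols_assoc_with_covariates(self, qtl_inputs):
        _, norm, coords, variants, positions, covs = qtl_inputs
        res = q.cis_scan(variants, positions, norm, coords, covs)
        feature = "ctss_0015"
        row = res[res.feature == feature].iloc[0]
        ref = st.ols_assoc(
            norm.loc[feature, variants.index], variants["H4"],
            covs.loc[variants.index].reset_index(drop=True),
        )
        assert row["t"] == pytest.approx(ref.t, abs=1e-8)

    def test_bh_fdr_is_monotone_step_up(self, qtl_inputs):
        _, norm, coords, variants, positions, covs = qtl_inputs
        res = q.cis_scan(variants, positions, norm, coords, covs)
        by_p = res.sort_values("p_nominal")
        assert (by_p["FDR"].diff().dropna() >= -1e-12).all()
        assert ((by_p["FDR"] > 0) & (by_p["FDR"] <= 1)).all()

    def test_empty_window_warns_and_returns_empty(self, qtl_inputs):
        _, norm, coords, variants, _, covs = qtl_inputs
        positions = pd.DataFrame({"variant": ["H4"], "chrom": "chr9", "pos": [1]})
        with pytest.warns(UserWarning, match="no variant-feature pairs"):
            res = q.cis_scan(variants, positions, norm, coords, covs)
        assert res.empty
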