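"""Association, GLM, EM D-prime and homozygote-carrier statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ctrich import simulate as sim
from ctrich import stats as st


@pytest.fixture(scope="module")
def cohort():
    return sim.simulate_cohort(sim.SimulationConfig(n_samples=1601, seed=101))


class TestOlsAssoc:
    def test_perfect_fit_when_outcome_equals_predictor(self):
        x = np.arange(20, dtype=float)
        res = st.ols_assoc(x, x)
        assert res.Rsq == pytest.approx(1.0, abs=1e-12)
        assert res.P < 1e-20

    def test_reproduces_pearson_correlation_t_test(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=300)
        y = 0.2 * x + rng.normal(size=300)
        res = st.ols_assoc(y, x)
        pr = sps.pearsonr(x, y)
        n = 300
        t_pearson = pr.statistic * math.sqrt((n - 2) / (1 - pr.statistic**2))
        assert res.t == pytest.approx(t_pearson, abs=1e-10)
        assert res.P == pytest.approx(pr.pvalue, abs=1e-10)

    def test_planted_effect_recovered_within_three_se(self, cohort):
        covs = cohort[list(st.DEFAULT_COVARIATES)]
        rng = np.random.default_rng(7)
        x = cohort["rs356182"].to_numpy(dtype=float)
        y = 0.3 * x + rng.normal(size=len(x))
        res = st.ols_assoc(y, x, covs)
        assert abs(res.beta - 0.3) <= 3 * res.SE

    def test_rank_deficient_design_names_collinear_column(self, cohort):
        covs = cohort[["sex", "age"]].copy()
        covs["sex_copy"] = covs["sex"]
        with pytest.raises(ValueError, match="sex_copy"):
            st.ols_assoc(cohort["dosage_H4"], cohort["rs356182"], covs)

    def test_too_few_complete_cases_raises(self):
        with pytest.raises(ValueError, match="complete cases"):
            st.ols_assoc([1.0, 2.0], [1.0, 2.0])

    def test_result_invariant_to_sample_permutation(self, cohort):
        covs = cohort[list(st.DEFAULT_COVARIATES)]
        res1 = st.ols_assoc(cohort["dosage_H4"], cohort["rs356182"], covs)
        perm = np.random.default_rng(3).permutation(len(cohort))
        res2 = st.ols_assoc(
            cohort["dosage_H4"].to_numpy()[perm],
            cohort["rs356182"].to_numpy()[perm],
            covs.iloc[perm].reset_index(drop=True),
        )
        assert res1.t == pytest.approx(res2.t, abs=1e-9)
        assert res1.Rsq == pytest.approx(res2.Rsq, abs=1e-9)


class TestLogisticAssoc:
    def test_planted_odds_ratio_recovered(self):
        cfg = sim.SimulationConfig(n_samples=20_000, seed=19)
        cohort = sim.simulate_cohort(cfg)
        res = st.logistic_assoc(
            cohort["phenotype"], cohort["rs356182"], cohort[list(st.DEFAULT_COVARIATES)]
        )
        assert abs(res.beta - math.log(1.05)) <= 3 * res.SE
        assert res.or_ci_low < res.OR < res.or_ci_high
        assert res.ci_low < res.beta < res.ci_high

    def test_single_class_phenotype_raises(self, cohort):
        with pytest.raises(ValueError, match="cases and controls"):
            st.logistic_assoc(np.ones(100), np.arange(100))

    def test_separation_raises_with_diagnostic(self):
        x = np.concatenate([np.zeros(50), np.ones(50) * 2])
        y = (x > 0).astype(float)
        with pytest.raises(ValueError, match="separation"):
            st.logistic_assoc(y, x)


class TestDprimeEm:
    def test_perfectly_coupled_loci_give_dprime_one(self):
        g = np.array([0, 1, 2] * 40)
        res = st.dprime_em(g, g)
        assert res.dprime == pytest.approx(1.0, abs=1e-9)
        assert np.all(res.frequencies >= 0)
        assert res.frequencies.sum() == pytest.approx(1.0, abs=1e-9)

    def test_independent_loci_give_near_zero_dprime(self):
        rng = np.random.default_rng(29)
        ga = rng.binomial(2, 0.3, size=10_000)
        gb = rng.binomial(2, 0.4, size=10_000)
        assert st.dprime_em(ga, gb).dprime < 0.05

    def test_em_equals_direct_counting_without_double_heterozygotes(self):
        """Phased-known oracle: duplicated gametes make every genotype pair
        unambiguous, so the EM MLE must equal plug-in phased counting."""
        rng = np.random.default_rng(37)
        freqs = sim.two_locus_frequencies(0.3, 0.2, 0.6)
        gam = rng.choice(4, size=800, p=freqs)
        a = (gam < 2).astype(int)  # carries focal allele
        b = ((gam == 0) | (gam == 2)).astype(int)
        phased = st.dprime_phased(a, b)
        em = st.dprime_em(2 * a, 2 * b)  # each sample = the same gamete twice
        assert em.dprime == pytest.approx(phased.dprime, abs=1e-6)

    def test_study_scale_recovery_of_reported_dprime(self):
        rng = np.random.default_rng(41)
        freqs = sim.two_locus_frequencies(0.08, 0.10, 0.76)
        gam = rng.choice(4, size=(1601, 2), p=freqs)
        ga = (gam < 2).sum(axis=1)
        gb = ((gam == 0) | (gam == 2)).sum(axis=1)
        res = st.dprime_em(ga, gb)
        se = st.bootstrap_dprime_se(ga, gb, rng=rng)
        assert abs(res.dprime - 0.76) <= 3 * se

    def test_monomorphic_locus_raises(self):
        with pytest.raises(ValueError, match="polymorphic"):
            st.dprime_em(np.zeros(50, dtype=int), np.tile([0, 1], 25))


class TestHomozygoteCarriers:
    @staticmethod
    def _frame(hap_dosages, snv):
        n = len(hap_dosages)
        df = pd.DataFrame({"sample_id": [f"S{i}" for i in range(n)]})
        for h in ("H1", "H2", "H3", "H4"):
            df[f"dosage_{h}"] = 0
        df["dosage_H3"] = hap_dosages
        snv_df = pd.DataFrame({"sample_id": df["sample_id"], "rsX": snv})
        return df, snv_df

    def test_hand_counted_percentage(self):
        assign, snv = self._frame([2, 2, 2, 2, 1], [1, 2, 1, 0, 2])
        table = st.homozygote_carrier_table(assign, snv)
        row = table[(table.haplotype == "H3") & (table.snv == "rsX")].iloc[0]
        assert row["percent"] == pytest.approx(75.0)
        assert row["n_homozygotes"] == 4 and row["n_carriers"] == 3

    def test_zero_homozygotes_not_estimable(self):
        assign, snv = self._frame([1, 1, 0], [1, 0, 1])
        table = st.homozygote_carrier_table(assign, snv)
        row = table[(table.haplotype == "H3")].iloc[0]
        assert not row["estimable"] and np.isnan(row["percent"])

    def test_complete_ld_forces_all_homozygotes_to_carry(self):
        cfg = sim.SimulationConfig(
            n_samples=2000,
            snv_specs=(sim.SnvSpec("rs_c", 0.3, 1.0, "H2"),),
            phenotype_model=sim.PhenotypeModel(log_odds={}),
            seed=53,
        )
        cohort = sim.simulate_cohort(cfg)
        hom = cohort[cohort["dosage_H2"] == 2]
        assert len(hom) > 0
        assert (hom["rs_c"] >= 1).all()

    def test_independent_snv_matches_closed_form(self):
        q = 0.4
        cfg = sim.SimulationConfig(
            n_samples=20_000,
            snv_specs=(sim.SnvSpec("rs_i", q, 0.0, "H2"),),
            phenotype_model=sim.PhenotypeModel(log_odds={}),
            seed=59,
        )
        cohort = sim.simulate_cohort(cfg)
        hom = cohort[cohort["dosage_H2"] == 2]
        expected = 1 - (1 - q) ** 2
        observed = (hom["rs_i"] >= 1).mean()
        se = math.sqrt(expected * (1 - expected) / len(hom))
        assert abs(observed - expected) <= 3 * se


class TestTableBuilders:
    def test_table_shapes_and_schema(self, cohort):
        snvs = ["rs356182", "rs2298728"]
        t1 = st.haplotype_snv_table(cohort, snvs)
        assert len(t1) == 8  # 4 haplotypes x 2 SNVs
        assert {"t", "P", "SE", "Rsq", "Dprime"} <= set(t1.columns)
        assert ((t1["P"] > 0) & (t1["P"] <= 1)).all()
        assert (t1["SE"] > 0).all()
        assert t1["Dprime"].between(0, 1).all()
        t2 = st.phenotype_table(cohort, snvs)
        assert len(t2) == 6  # 4 haplotypes + 2 SNVs
        assert (t2["OR"] > 0).all()
        assert (t2["ci_low"] < t2["ci_high"]).all()

    def test_linked_snv_shows_positive_association_with_its_haplotype(self, cohort):
        t1 = st.haplotype_snv_table(cohort, ["rs2298728"])
        row = t1[(t1.haplotype == "H3")].iloc[0]
        assert row["t"] > 5  # strong positive tagging by construction
        assert row["Dprime"] > 0.5
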