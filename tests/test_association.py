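"""Residualization, PCA/LD utilities, single-variant and conditional tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rarelocus as rl
from conftest import make_matrix
from rarelocus.association import ols_fit
from rarelocus.containers import MISSING
from rarelocus.simulate import correlated_dosages, simulate_covariates


def _phenotable(n, rng, trait_fn=None):
    cov = simulate_covariates(rl.SimulationConfig(n_individuals=max(n, 50), seed=5))
    cov = cov.iloc[:n].copy()
    for t in rl.containers.TRAITS:
        cov[t] = rng.normal(5.0, 1.0, size=n)
    if trait_fn is not None:
        cov = trait_fn(cov)
    return cov


class TestResidualize:
    def test_perfect_covariate_prediction_gives_zero_residuals(self, rng):
        ph = _phenotable(300, rng)
        age_c = ph["age"] - 45.0
        ph["TC"] = 1.0 + 0.02 * age_c + 0.3 * ph["sex"]
        res = rl.residualize(ph, "TC")
        assert np.allclose(res.residuals.to_numpy(), 0.0, atol=1e-10)
        assert res.transformation == "none"

    def test_covariate_coefficient_recovery_coverage(self, rng):
        """Planted covariate betas are recovered within their 95% CIs at the
        expected rate over replicates."""
        hits = total = 0
        for _ in range(60):
            ph = _phenotable(400, rng)
            age_c = ph["age"] - 45.0
            ph["TC"] = 2.0 + 0.05 * age_c + 0.4 * ph["sex"] + rng.normal(0, 1, 400)
            X = np.column_stack([np.ones(400), age_c, age_c**2, ph["sex"],
                                 ph["oc_use"], ph["pregnant"],
                                 ph["cohort"].str.startswith("cohortB").astype(float)])
            keep = [i for i in range(X.shape[1]) if np.std(X[:, i]) > 0 or i == 0]
            beta, se, _, _, _, _ = ols_fit(X[:, keep], ph["TC"].to_numpy())
            if abs(beta[1] - 0.05) < 1.96 * se[1]:
                hits += 1
            total += 1
        assert hits / total >= 0.85

    def test_log_traits_transformed_and_positive_enforced(self, rng):
        ph = _phenotable(100, rng)
        ph["TG"] = np.exp(rng.normal(0, 0.4, size=100))
        res = rl.residualize(ph, "TG")
        assert res.transformation == "log"
        ph.loc[ph.index[0], "TG"] = -1.0
        with pytest.raises(ValueError, match="non-positive"):
            rl.residualize(ph, "TG")

    def test_t2d_cases_excluded_from_glycemic_traits(self, rng):
        ph = _phenotable(200, rng)
        ph["FG"] = np.exp(rng.normal(1.6, 0.1, 200))
        res = rl.residualize(ph, "FG")
        cases = set(ph.loc[ph["case_status"] == 1, "id"])
        assert cases
        assert cases.isdisjoint(set(res.residuals.index))
        assert set(res.excluded.loc[res.excluded["reason"] == "T2D-case", "id"]) == cases
        # but not from a lipid trait
        res2 = rl.residualize(ph, "TC")
        assert cases <= set(res2.residuals.index)

    def test_inverse_normal_residuals_are_standard_normal(self, rng):
        ph = _phenotable(5_000, rng)
        ph["TC"] = np.exp(rng.normal(0, 1, 5_000))  # heavily skewed
        res = rl.residualize(ph, "TC", transform="inverse-normal")
        ks = stats.kstest(res.residuals.to_numpy(), "norm")
        assert ks.pvalue > 0.01

    def test_residuals_mean_zero(self, rng):
        ph = _phenotable(500, rng)
        res = rl.residualize(ph, "HDLC")
        assert abs(res.residuals.mean()) < 1e-10


class TestLdAndPca:
    def test_duplicate_snp_pruned(self, rng):
        d = rng.binomial(2, 0.3, size=(100, 1)).astype(np.int8)
        G = make_matrix(np.column_stack([d, d, rng.binomial(2, 0.3, size=(100, 1))]))
        kept = rl.ld_prune(G, r2_max=0.5)
        assert 0 in kept and 1 not in kept and 2 in kept

    def test_ld_r2_basics_and_boundary(self, rng):
        a = rng.binomial(2, 0.3, size=2_000).astype(float)
        assert rl.ld_r2(a, a) == pytest.approx(1.0)
        assert rl.independence_check(0.19)
        assert not rl.independence_check(0.20)
        mono = np.zeros(2_000)
        assert np.isnan(rl.ld_r2(a, mono))
        with pytest.raises(ValueError):
            rl.ld_r2(a[:10], a[:10])  # too few overlapping pairs

    def test_independent_snps_have_near_zero_r2(self, rng):
        vals = [
            rl.ld_r2(rng.binomial(2, 0.3, 6_000).astype(float),
                     rng.binomial(2, 0.3, 6_000).astype(float))
            for _ in range(100)
        ]
        assert np.mean(vals) < 0.01

    def test_pca_separates_planted_substructure(self):
        cfg = rl.SimulationConfig(n_individuals=400, seed=21, substructure_fst=0.01)
        rng = np.random.default_rng(1)
        f = np.clip(rl.simulate_allele_frequencies(cfg, n_sites=500), 0.05, 0.5)
        G = rl.simulate_genotypes(f, cfg)
        pcs = rl.genotype_pca(G, K=2)
        labels = pd.Series(rl.simulate.assign_cohorts(cfg)).str.startswith("cohortB")
        r = np.corrcoef(pcs.scores[:, 0], labels.to_numpy(float))[0, 1]
        assert abs(r) > 0.5

    def test_pca_k_exceeding_rank_fatal(self, rng):
        G = make_matrix(rng.binomial(2, 0.3, size=(10, 4)).astype(np.int8))
        with pytest.raises(ValueError, match="rank"):
            rl.genotype_pca(G, K=8)


class TestSingleVariant:
    def _run(self, rng, n=600, beta=0.0, maf=0.2, pcs=None, model="additive"):
        d = rng.binomial(2, maf, size=n).astype(np.int8)
        y = beta * d + rng.normal(size=n)
        res = pd.Series(y, index=[f"I{i:06d}" for i in range(n)])
        return rl.single_variant_test(
            res, d, list(res.index), pcs=pcs, model=model, variant_id="v", trait="TC"
        )

    def test_null_type_i_error_calibrated(self, rng):
        rejections = sum(self._run(rng).p < 0.05 for _ in range(1_000))
        rate = rejections / 1_000
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 1_000)

    def test_planted_beta_unbiased(self, rng):
        betas = [self._run(rng, n=2_000, beta=0.3).beta for _ in range(200)]
        assert abs(np.mean(betas) - 0.3) < 0.05 * 0.3

    def test_misspecified_recessive_coding_loses_power(self, rng):
        """A dominant-simulated effect tested under recessive coding yields
        systematically weaker evidence than under dominant coding."""
        wins = 0
        for _ in range(60):
            n = 800
            d = rng.binomial(2, 0.3, size=n).astype(np.int8)
            y = 0.3 * (d >= 1) + rng.normal(size=n)
            res = pd.Series(y, index=[f"I{i:06d}" for i in range(n)])
            ids = list(res.index)
            p_dom = rl.single_variant_test(res, d, ids, model="dominant").p
            p_rec = rl.single_variant_test(res, d, ids, model="recessive").p
            wins += p_dom < p_rec
        assert wins / 60 > 0.7

    def test_monomorphic_and_maf_floor_flags(self, rng):
        n = 500
        res = pd.Series(rng.normal(size=n), index=[f"I{i:06d}" for i in range(n)])
        ids = list(res.index)
        out = rl.single_variant_test(res, np.zeros(n, dtype=np.int8), ids)
        assert out.flag == "monomorphic"
        d = np.zeros(n, dtype=np.int8)
        d[0] = 1  # MAF 0.001 = floor, excluded by strict >
        out = rl.single_variant_test(res, d, ids)
        assert out.flag == "below-maf-floor"

    def test_missing_dosages_dropped_complete_case(self, rng):
        n = 400
        d = rng.binomial(2, 0.3, size=n).astype(np.int8)
        d[:50] = MISSING
        res = pd.Series(rng.normal(size=n), index=[f"I{i:06d}" for i in range(n)])
        out = rl.single_variant_test(res, d, list(res.index))
        assert out.n == 350


class TestConditional:
    def _ids(self, n):
        return [f"I{i:06d}" for i in range(n)]

    def test_perfect_ld_flags_collinear(self, rng):
        n = 500
        d = rng.binomial(2, 0.3, size=n).astype(np.int8)
        res = pd.Series(rng.normal(size=n), index=self._ids(n))
        out = rl.conditional_test(res, d, d, self._ids(n))
        assert out.flag == "collinear-with-covariate"

    def test_constant_zero_array_covariate_equals_unconditional(self, rng):
        n = 500
        d = rng.binomial(2, 0.3, size=n).astype(np.int8)
        res = pd.Series(rng.normal(size=n), index=self._ids(n))
        cond = rl.conditional_test(res, d, np.zeros(n, dtype=np.int8), self._ids(n))
        marg = rl.single_variant_test(res, d, self._ids(n))
        assert cond.beta == pytest.approx(marg.beta, abs=1e-12)
        assert cond.p == pytest.approx(marg.p, abs=1e-12)

    def test_independent_signal_unchanged_by_conditioning(self, rng):
        diffs = []
        for _ in range(40):
            n = 2_000
            arr = rng.binomial(2, 0.3, size=n).astype(np.int8)
            snp = rng.binomial(2, 0.05, size=n).astype(np.int8)
            y = 0.1 * arr + 0.25 * snp + rng.normal(size=n)
            res = pd.Series(y, index=self._ids(n))
            marg = rl.single_variant_test(res, snp, self._ids(n))
            cond = rl.conditional_test(res, snp, arr, self._ids(n))
            diffs.append(abs(np.log10(cond.p) - np.log10(marg.p)))
        assert np.median(diffs) < 0.5

    def test_ld_mediated_signal_absorbed_by_conditioning(self, rng):
        cond_ps, marg_ps = [], []
        for _ in range(40):
            n = 2_000
            arr, snp = correlated_dosages(0.3, np.sqrt(0.8), n, rng)
            y = 0.15 * arr + rng.normal(size=n)  # no direct effect of snp
            res = pd.Series(y, index=self._ids(n))
            marg_ps.append(rl.single_variant_test(res, snp, self._ids(n)).p)
            cond_ps.append(rl.conditional_test(res, snp, arr, self._ids(n)).p)
        # marginal sees the LD shadow; conditional is null-like
        assert np.median(marg_ps) < 0.01
        assert 0.15 < np.median(cond_ps) < 0.85

    def test_conditioned_on_recorded(self, rng):
        n = 300
        d = rng.binomial(2, 0.3, size=n).astype(np.int8)
        a = rng.binomial(2, 0.3, size=n).astype(np.int8)
        res = pd.Series(rng.normal(size=n), index=self._ids(n))
        out = rl.conditional_test(res, d, a, self._ids(n), array_id="rs1")
        assert out.conditioned_on == ["rs1"]


class TestArraySnpSelection:
    def _mk(self, vid, p):
        return rl.association.SingleVariantResult(
            vid, "TC", "additive", 0.1, 0.02, p, 0.3, 100
        )

    def test_argmin_matches_brute_force(self, rng):
        ps = rng.uniform(size=20)
        results = [self._mk(f"G:1:{1000 + i}", p) for i, p in enumerate(ps)]
        assert rl.select_array_snp(results) == results[int(np.argmin(ps))].variant_id

    def test_single_candidate_and_empty(self):
        only = self._mk("G:1:5", 0.2)
        assert rl.select_array_snp([only]) == "G:1:5"
        with pytest.raises(ValueError):
            rl.select_array_snp([])

    def test_tie_broken_by_position(self):
        a = self._mk("G:1:2000", 0.01)
        b = self._mk("G:1:1000", 0.01)
        assert rl.select_array_snp([a, b]) == "G:1:1000"


class TestCaseControl:
    def test_planted_log_or_recovered(self, rng):
        hits = 0
        for _ in range(60):
            n = 3_000
            d = rng.binomial(2, 0.2, size=n).astype(np.int8)
            logit = -1.2 + 0.3 * d
            y = rng.uniform(size=n) < 1 / (1 + np.exp(-logit))
            out = rl.case_control_test(y.astype(int), d, variant_id="v")
            if abs(out.beta - 0.3) < 1.96 * out.se:
                hits += 1
        assert hits / 60 >= 0.85

    def test_null_calibration(self, rng):
        rej = 0
        reps = 400
        for _ in range(reps):
            n = 800
            d = rng.binomial(2, 0.2, size=n).astype(np.int8)
            y = rng.integers(0, 2, size=n)
            out = rl.case_control_test(y, d)
            rej += out.p < 0.05
        assert abs(rej / reps - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps) + 0.01

    def test_monomorphic_skipped(self):
        y = np.array([1, 1, 0, 0])
        out = rl.case_control_test(y, np.zeros(4, dtype=np.int8))
        assert out.flag == "monomorphic"

    def test_maf_floor(self, rng):
        n = 1_000
        d = np.zeros(n, dtype=np.int8)
        d[:10] = 1  # MAF 0.5% < 1% floor
        y = rng.integers(0, 2, size=n)
        assert rl.case_control_test(y, d).flag == "below-maf-floor"


class TestRegressionEquivalence:
    def test_residualize_then_regress_matches_joint_fit(self, rng):
        """With the genotype orthogonalized against the covariates, the
        two-stage residual regression and the joint fit give the same
        genotype beta to numerical tolerance."""
        n = 1_000
        ph = _phenotable(n, rng)
        age_c = (ph["age"] - 45.0).to_numpy()
        Z = np.column_stack([np.ones(n), age_c, ph["sex"].to_numpy(float)])
        d = rng.binomial(2, 0.3, size=n).astype(float)
        y = 0.1 * d + 0.03 * age_c + rng.normal(size=n)
        # orthogonalize genotype against covariates
        d_t = d - Z @ np.linalg.lstsq(Z, d, rcond=None)[0]
        resid = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        beta_two_stage = np.linalg.lstsq(
            np.column_stack([np.ones(n), d_t]), resid, rcond=None
        )[0][1]
        beta_joint = np.linalg.lstsq(
            np.column_stack([Z, d_t]), y, rcond=None
        )[0][-1]
        assert beta_two_stage == pytest.approx(beta_joint, abs=1e-6)
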