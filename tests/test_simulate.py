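"""Synthetic-cohort generator: frequency model, genotypes, phenotypes,
replicate call sets, and the planted ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import rarelocus as rl
from rarelocus.simulate import (
    correlated_dosages,
    sample_maf,
    simulate_center_callsets,
    simulate_covariates,
    stage_rng,
)


def _sfs_from_freqs(freqs, n_chrom, rng):
    """Observed folded SFS after binomially sampling n_chrom chromosomes."""
    counts = rng.binomial(n_chrom, freqs)
    counts = np.minimum(counts, n_chrom - counts)
    counts = counts[counts > 0]
    return np.bincount(counts, minlength=n_chrom // 2 + 1)[1:]


class TestAlleleFrequencies:
    def test_folded_range(self):
        cfg = rl.SimulationConfig(n_individuals=200, seed=1)
        f = rl.simulate_allele_frequencies(cfg, n_sites=2000)
        assert f.shape == (2000,)
        assert np.all((f > 0) & (f <= 0.5))

    def test_neutral_limit_matches_binomial_mixture_oracle(self):
        """Without a bottleneck the sampled folded SFS matches the 1/p
        frequency-density prediction (with the generator's condition-on-
        segregating acceptance factor), computed by numerical integration:
        E[eta_j] ~ int C(n,j) p^j (1-p)^(n-j) (1-(1-p)^n) / p dp."""
        n_ind = 100
        n_chrom = 2 * n_ind
        cfg = rl.SimulationConfig(
            n_individuals=n_ind, seed=2,
            bottleneck=rl.BottleneckSpec(enabled=False),
        )
        rng = stage_rng(cfg.seed, "genotypes")
        f = rl.simulate_allele_frequencies(cfg, n_sites=40_000)
        obs = _sfs_from_freqs(f, n_chrom, rng)

        p_min = 1.0 / (4.0 * n_ind)
        def expected_mass(j):
            val, _ = integrate.quad(
                lambda p: stats.binom.pmf(j, n_chrom, p)
                * -np.expm1(n_chrom * np.log1p(-p)) / p,
                p_min, 0.5, limit=200,
            )
            return val
        bins = np.arange(1, 11)
        exp = np.array([expected_mass(j) for j in bins])
        exp /= exp.sum()
        got = obs[:10] / obs[:10].sum()
        se = np.sqrt(exp * (1 - exp) / obs[:10].sum())
        assert np.all(np.abs(got - exp) < 4 * se + 0.01)

    def test_bottleneck_enriches_goldilocks_and_depletes_singletons(self):
        """Paired comparison at matched sample size: the bottleneck spectrum
        has more 0.5-2% MAF sites and fewer singletons than the neutral run."""
        n_ind = 500
        base = dict(n_individuals=n_ind, seed=5)
        cfg_b = rl.SimulationConfig(**base)
        cfg_n = rl.SimulationConfig(**base, bottleneck=rl.BottleneckSpec(enabled=False))
        fb = rl.simulate_allele_frequencies(cfg_b, n_sites=10_000)
        fn = rl.simulate_allele_frequencies(cfg_n, n_sites=10_000)
        rng = np.random.default_rng(99)
        n_chrom = 2 * n_ind
        for label, f in (("bottleneck", fb), ("neutral", fn)):
            counts = rng.binomial(n_chrom, f)
            counts = np.minimum(counts, n_chrom - counts)
            counts = counts[counts > 0]
            maf = counts / n_chrom
            frac_goldi = np.mean((maf >= 0.005) & (maf <= 0.02))
            frac_single = np.mean(counts == 1)
            if label == "bottleneck":
                gb, sb = frac_goldi, frac_single
            else:
                gn, sn = frac_goldi, frac_single
        assert gb > gn
        assert sb < sn

    def test_wright_fisher_mode_runs_and_rejects_bad_bottleneck(self):
        cfg = rl.SimulationConfig(
            n_individuals=100, seed=3,
            bottleneck=rl.BottleneckSpec(
                mode="wright_fisher", ancestral_size=2000,
                bottleneck_size=50, generations_post=20,
            ),
        )
        f = rl.simulate_allele_frequencies(cfg, n_sites=500)
        assert np.all((f > 0) & (f <= 0.5))
        with pytest.raises(ValueError):
            rl.SimulationConfig(
                n_individuals=100,
                bottleneck=rl.BottleneckSpec(mode="wright_fisher", bottleneck_size=1),
            ).validate()


class TestGenotypes:
    def test_mean_dosage_at_half_frequency(self):
        cfg = rl.SimulationConfig(n_individuals=10_000, seed=4)
        G = rl.simulate_genotypes(np.array([0.5]), cfg)
        mean = G.dosages.mean()
        sd = np.sqrt(2 * 0.5 * 0.5 / 10_000)
        assert abs(mean - 1.0) < 3 * sd

    def test_hardy_weinberg_heterozygote_fraction(self):
        cfg = rl.SimulationConfig(n_individuals=20_000, seed=6)
        p = 0.2
        G = rl.simulate_genotypes(np.array([p]), cfg)
        het = np.mean(G.dosages == 1)
        expect = 2 * p * (1 - p)
        assert abs(het - expect) < 3 * np.sqrt(expect * (1 - expect) / 20_000)

    def test_sample_maf_is_consistent(self):
        cfg = rl.SimulationConfig(n_individuals=5_000, seed=7)
        freqs = np.array([0.01, 0.05, 0.3, 0.5])
        G = rl.simulate_genotypes(freqs, cfg, variants=None)
        est = sample_maf(G.dosages)
        se = np.sqrt(freqs * (1 - freqs) / (2 * 5_000))
        assert np.all(np.abs(est - freqs) < 4 * se)

    def test_rejects_unfolded_frequencies(self):
        cfg = rl.SimulationConfig(n_individuals=100, seed=1)
        with pytest.raises(ValueError):
            rl.simulate_genotypes(np.array([0.7]), cfg)

    def test_no_substructure_means_no_cohort_separation(self):
        """At Fst=0, PC1 correlates with cohort labels no more than with
        permuted labels."""
        cfg = rl.SimulationConfig(n_individuals=400, seed=8, substructure_fst=0.0)
        f = rl.simulate_allele_frequencies(cfg, n_sites=300)
        f = np.clip(f, 0.05, 0.5)  # common SNPs for a stable PCA
        G = rl.simulate_genotypes(f, cfg)
        pcs = rl.genotype_pca(G, K=2)
        labels = (
            pd.Series(rl.simulate.assign_cohorts(cfg))
            .str.startswith("cohortB").to_numpy(float)
        )
        obs = abs(np.corrcoef(pcs.scores[:, 0], labels)[0, 1])
        rng = np.random.default_rng(0)
        null = [
            abs(np.corrcoef(pcs.scores[:, 0], rng.permutation(labels))[0, 1])
            for _ in range(200)
        ]
        assert obs < np.quantile(null, 0.995)

    def test_correlated_dosages_hit_target_r2(self, rng):
        r = np.sqrt(0.8)
        a, b = correlated_dosages(0.3, r, 20_000, rng)
        r2 = np.corrcoef(a.astype(float), b.astype(float))[0, 1] ** 2
        assert abs(r2 - 0.8) < 0.03


class TestPhenotypes:
    def test_null_effects_give_uniform_pvalues(self, rng):
        """With all genetic betas zero, regressing the trait on any dosage
        yields uniform p-values across simulation replicates."""
        pvals = []
        for rep in range(200):
            n = 150
            d = rng.binomial(2, 0.2, size=n).astype(float)
            y = rng.normal(size=n)
            X = np.column_stack([np.ones(n), d])
            _, _, _, p, _, _ = rl.association.ols_fit(X, y)
            pvals.append(p[1])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001

    def test_planted_beta_ci_coverage(self, rng):
        """95% CI of the single-variant estimate covers the planted 0.3-SD
        effect in about 95% of replicates."""
        hits = 0
        reps = 200
        n = 2_000
        for _ in range(reps):
            d = rng.binomial(2, 0.05, size=n).astype(float)
            y = 0.3 * d + rng.normal(size=n)
            X = np.column_stack([np.ones(n), d])
            beta, se, _, _, _, _ = rl.association.ols_fit(X, y)
            if abs(beta[1] - 0.3) < 1.96 * se[1]:
                hits += 1
        assert hits / reps >= 0.93

    def test_log_traits_linear_on_log_scale(self, small_cohort):
        ph = small_cohort.phenotypes
        for t in ("TG", "FG", "FI"):
            assert (ph[t] > 0).all()
        assert not (ph["TC"] <= 0).all()

    def test_rejects_negative_residual_sd(self, small_cohort):
        cfg = rl.SimulationConfig(n_individuals=100)
        cfg.residual_sd["TC"] = -1.0
        with pytest.raises(ValueError):
            rl.simulate_phenotypes(
                small_cohort.genotypes, rl.TrueModel(), cfg
            )

    def test_rejects_unknown_causal_variant(self, small_cohort):
        cfg = rl.SimulationConfig(n_individuals=500)
        bad = rl.TrueModel(betas={"TC": {"NOPE:1:1": 0.5}})
        with pytest.raises(ValueError, match="NOPE"):
            rl.simulate_phenotypes(small_cohort.genotypes, bad, cfg)

    def test_variance_explained_ledger_bounded(self, small_cohort):
        for trait, d in small_cohort.true_model.variance_explained.items():
            assert 0 <= sum(d.values()) <= 1

    def test_array_snp_variance_matches_closed_form(self, rng):
        """Downstream R^2 of the array SNP approximates 2p(1-p)beta^2/Var."""
        n, p, beta = 20_000, 0.3, 0.15
        d = rng.binomial(2, p, size=n).astype(float)
        y = beta * d + rng.normal(size=n)
        expected = 2 * p * (1 - p) * beta**2 / (1 + 2 * p * (1 - p) * beta**2)
        r2 = np.corrcoef(d, y)[0, 1] ** 2
        assert abs(r2 - expected) < 0.01


class TestCenterCallsets:
    def test_noiseless_centers_equal_truth(self, small_cohort):
        cfg = rl.SimulationConfig(
            n_individuals=small_cohort.config.n_individuals,
            seed=1, center_error_rate=0.0, center_missing_rate=0.0,
        )
        sets = simulate_center_callsets(small_cohort.genotypes, cfg)
        assert len(sets) == 3
        for cs in sets:
            assert np.array_equal(cs.dosages, small_cohort.genotypes.dosages)

    def test_single_disagreement_rate_matches_binomial(self, rng):
        """P(exactly one of three centers flips a genotype) = 3 e (1-e)^2."""
        e = 0.02
        n, m = 400, 120
        from conftest import make_variants

        truth = rl.GenotypeMatrix(
            rng.binomial(2, 0.3, size=(n, m)).astype(np.int8),
            [f"I{i:06d}" for i in range(n)],
            make_variants(m),
        )
        cfg = rl.SimulationConfig(
            n_individuals=n, seed=9, center_error_rate=e, center_missing_rate=0.0
        )
        sets = simulate_center_callsets(truth, cfg, rng=rng)
        stack = np.stack([cs.dosages for cs in sets])
        diffs = (stack != truth.dosages[None]).sum(axis=0)
        frac_one = np.mean(diffs == 1)
        expect = 3 * e * (1 - e) ** 2
        se = np.sqrt(expect * (1 - expect) / (n * m))
        assert abs(frac_one - expect) < 4 * se

    def test_fixed_seed_reproducibility(self, small_config):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = rl.generate_cohort(small_config)
            b = rl.generate_cohort(small_config)
        for csa, csb in zip(a.center_callsets, b.center_callsets):
            assert np.array_equal(csa.dosages, csb.dosages)
            assert csa.variants.equals(csb.variants)
        assert a.phenotypes.equals(b.phenotypes)

    def test_substreams_are_stage_independent(self):
        a = stage_rng(42, "phenotypes").normal(size=5)
        b = stage_rng(42, "phenotypes").normal(size=5)
        c = stage_rng(42, "genotypes").normal(size=5)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestCovariates:
    def test_oc_and_pregnancy_female_only(self):
        cov = simulate_covariates(rl.SimulationConfig(n_individuals=2_000, seed=12))
        males = cov["sex"] == 0
        assert cov.loc[males, "oc_use"].sum() == 0
        assert cov.loc[males, "pregnant"].sum() == 0
        assert cov["age"].between(31, 62).all()

    def test_cohort_fractions_respected(self):
        cfg = rl.SimulationConfig(n_individuals=6123, seed=1)
        cov = simulate_covariates(cfg)
        counts = cov["cohort"].value_counts()
        assert counts["cohortA"] == 4447
        assert counts["cohortB-control"] == 836
        assert counts["cohortB-case"] == 840

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            rl.SimulationConfig(n_individuals=10).validate()
        cfg = rl.SimulationConfig()
        cfg.cohort_fractions = {"cohortA": 0.5, "cohortB-control": 0.2, "cohortB-case": 0.2}
        with pytest.raises(ValueError):
            cfg.validate()
        with pytest.raises(ValueError):
            rl.SimulationConfig(center_error_rate=1.5).validate()
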