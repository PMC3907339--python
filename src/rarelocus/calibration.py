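"""Monte-Carlo calibration experiments for the gene-level and model-selection
machinery.

These are the package's operating-characteristic checks: type-I error of the
CMC and SKAT tests on null synthetic gene sets, the burden-vs-variance-
component power ordering under same-direction and mixed-direction rare-variant
architectures, agreement of SKAT's asymptotic p-values with permutation,
conditional-analysis behaviour under planted LD, and greedy-BIC recovery of
planted multi-variant models. Each function is seeded and returns plain
numbers so it can back both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .association import conditional_test, single_variant_test
from .containers import GenotypeMatrix
from .genetest import GeneVariantSet, cmc_test, skat_permutation_pvalues, skat_test
from .selection import greedy_bic_select
from .simulate import correlated_dosages


def _ids(n: int) -> list[str]:
    return [f"I{i:06d}" for i in range(n)]


def _null_gene_set(
    rng: np.random.Generator, n: int, m: int,
    maf_lo: float = 0.002, maf_hi: float = 0.01,
) -> GeneVariantSet:
    """A rare-variant gene set with no phenotype effect attached."""
    while True:
        p = rng.uniform(maf_lo, maf_hi, size=m)
        geno = rng.binomial(2, p, size=(n, m)).astype(np.int8)
        poly = geno.sum(0) > 0
        if poly.sum() >= 2:
            geno = geno[:, poly]
            break
    return GeneVariantSet(
        "GENE", [f"GENE:1:{j}" for j in range(geno.shape[1])],
        geno, _ids(n), geno.mean(0) / 2,
    )


def _residuals(y: np.ndarray) -> pd.Series:
    return pd.Series(np.asarray(y, float), index=_ids(len(y)))


def cmc_skat_type1(
    n_genes: int = 1_000, n: int = 400, m: int = 8,
    B: int = 1_000, alpha: float = 0.05, seed: int = 0,
) -> dict[str, float]:
    """Empirical rejection rates of CMC (permutation) and SKAT (asymptotic)
    at level alpha over null gene sets with Gaussian traits."""
    rng = np.random.default_rng(seed)
    cmc_rej = skat_rej = 0
    for g in range(n_genes):
        gs = _null_gene_set(rng, n, m)
        res = _residuals(rng.normal(size=n))
        _, p_cmc, _ = cmc_test(gs, res, B=B, seed=seed * 100_003 + g, escalate_to=B)
        _, p_skat = skat_test(gs, res)
        cmc_rej += p_cmc <= alpha
        skat_rej += p_skat <= alpha
    return {
        "cmc_type1": cmc_rej / n_genes,
        "skat_type1": skat_rej / n_genes,
        "mc_se": float(np.sqrt(alpha * (1 - alpha) / n_genes)),
        "n_genes": n_genes,
    }


def power_ordering(
    reps: int = 200, n: int = 1_500, m: int = 8,
    effect_sd: float = 0.25, B: int = 2_000, seed: int = 1,
) -> dict[str, float]:
    """Fraction of replicates in which the better-matched test wins.

    Same-direction architecture (every causal allele shifts the trait the
    same way): the burden test should give the smaller p-value. Mixed
    directions (alternating signs): SKAT should. Effect sizes are chosen so
    typical p-values sit inside the permutation-resolvable range.
    """
    rng = np.random.default_rng(seed)
    wins = {"same": 0, "mixed": 0}
    for mode in ("same", "mixed"):
        for r in range(reps):
            gs = _null_gene_set(rng, n, m, maf_lo=0.002, maf_hi=0.01)
            signs = np.ones(gs.n_variants)
            if mode == "mixed":
                signs[1::2] = -1.0
                betas = 1.4 * effect_sd * signs
            else:
                betas = effect_sd * signs
            y = gs.genotypes @ betas + rng.normal(size=n)
            res = _residuals(y)
            _, p_cmc, _ = cmc_test(
                gs, res, B=B, seed=seed * 7919 + r, escalate_to=10 * B
            )
            _, p_skat = skat_test(gs, res)
            if mode == "same":
                wins[mode] += p_cmc < p_skat
            else:
                wins[mode] += p_skat < p_cmc
    return {
        "cmc_beats_skat_same_direction": wins["same"] / reps,
        "skat_beats_cmc_mixed_direction": wins["mixed"] / reps,
        "reps": reps,
    }


def skat_asymptotic_vs_permutation(
    n_genes: int = 200, n: int = 500, m: int = 10,
    B: int = 2_000, seed: int = 2,
) -> dict[str, float]:
    """Spearman rank correlation between SKAT asymptotic and permutation
    p-values over null genes."""
    rng = np.random.default_rng(seed)
    asym, perm = [], []
    for g in range(n_genes):
        gs = _null_gene_set(rng, n, m, maf_lo=0.002, maf_hi=0.02)
        res = _residuals(rng.normal(size=n))
        asym.append(skat_test(gs, res)[1])
        perm.append(
            skat_permutation_pvalues(gs, res, B=B, seed=seed * 4409 + g)
        )
    rho = stats.spearmanr(asym, perm).statistic
    return {"rank_correlation": float(rho), "n_genes": n_genes}


def conditional_separation(
    reps: int = 50, n: int = 2_000, seed: int = 3
) -> dict[str, float]:
    """Conditional analysis under two planted LD regimes.

    Independent regime (r^2 = 0 with the array SNP, direct effect): the
    conditional p-value should match the marginal one. Mediated regime
    (r^2 = 0.8 with the array SNP, no direct effect): the marginal signal is
    an LD shadow and the conditional p-value distribution should revert
    toward uniform.
    """
    rng = np.random.default_rng(seed)
    ids = _ids(n)
    log_diffs, mediated_cond, mediated_marg = [], [], []
    for _ in range(reps):
        arr = rng.binomial(2, 0.3, size=n).astype(np.int8)
        snp = rng.binomial(2, 0.05, size=n).astype(np.int8)
        y = 0.1 * arr + 0.25 * snp + rng.normal(size=n)
        res = _residuals(y)
        p_m = single_variant_test(res, snp, ids).p
        p_c = conditional_test(res, snp, arr, ids).p
        log_diffs.append(abs(np.log10(p_c) - np.log10(p_m)))

        arr2, shadow = correlated_dosages(0.3, np.sqrt(0.8), n, rng)
        y2 = 0.15 * arr2 + rng.normal(size=n)
        res2 = _residuals(y2)
        mediated_marg.append(single_variant_test(res2, shadow, ids).p)
        mediated_cond.append(conditional_test(res2, shadow, arr2, ids).p)
    return {
        "independent_median_log10_shift": float(np.median(log_diffs)),
        "mediated_marginal_median_p": float(np.median(mediated_marg)),
        "mediated_conditional_median_p": float(np.median(mediated_cond)),
        "reps": reps,
    }


def bic_recovery(
    reps: int = 25, n: int = 5_000, m: int = 50,
    variance_each: float = 0.005, seed: int = 4,
) -> dict[str, float]:
    """Fraction of replicates in which greedy BIC recovers all three planted
    independent variants, each explaining ``variance_each`` of the trait."""
    rng = np.random.default_rng(seed)
    hits = 0
    causal = [5, 20, 41]
    p_maf = 0.2
    beta = np.sqrt(variance_each / (2 * p_maf * (1 - p_maf)))
    for _ in range(reps):
        dos = rng.binomial(2, p_maf, size=(n, m)).astype(np.int8)
        var = pd.DataFrame(
            {
                "variant_id": [f"L:1:{1000 + j}" for j in range(m)],
                "chrom": "1", "pos": [1000 + j for j in range(m)],
                "ref": "A", "alt": "C", "gene": "L",
                "consequence": "missense_benign", "is_array_snp": False,
            }
        )
        G = GenotypeMatrix(dos, _ids(n), var)
        y = rng.normal(size=n)
        for j in causal:
            y = y + beta * dos[:, j]
        sel = greedy_bic_select(_residuals(y), G)
        want = {f"L:1:{1000 + j}" for j in causal}
        hits += want <= set(sel.selected)
    return {"recovery_rate": hits / reps, "reps": reps}
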