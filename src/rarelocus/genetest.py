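"""Gene-level rare-variant association: CMC burden and SKAT score tests.

CMC collapses a gene's rare non-synonymous variants into one weighted-sum
burden score per individual (inverse-SD Madsen-Browning weights by default)
and tests its regression coefficient; because the score's null distribution
under the realized genotype configuration is awkward at low carrier counts,
its p-value comes from permutations of the phenotype residuals.

SKAT tests the variance of a random-effects distribution over per-variant
effect sizes: the score statistic Q = r' G W^2 G' r is, under the null, a
weighted mixture of 1-df chi-squares whose weights are the eigenvalues of
W G' P G W (P the null-model projection). The mixture tail probability is
evaluated by Imhof characteristic-function inversion with a Liu
moment-matching fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .containers import MISSING, NONSYNONYMOUS, GenotypeMatrix

GENE_MAF_MAX = 0.01
MIN_VARIANTS = 2


@dataclass
class GeneVariantSet:
    """A gene's qualifying rare-variant genotypes, complete-case restricted."""

    gene: str
    variant_ids: list[str]
    genotypes: np.ndarray  # (n_complete, m) dosages, no missing values
    individuals: list[str]
    mafs: np.ndarray

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class GeneTestResult:
    gene: str
    trait: str
    n: int
    n_variants: int
    cmc_stat: float
    cmc_p: float
    cmc_B: int
    skat_Q: float
    skat_p: float
    n_up: int
    n_down: int
    flag: str = ""


def build_gene_sets(
    G: GenotypeMatrix,
    annotations: pd.DataFrame | None = None,
    maf_max: float = GENE_MAF_MAX,
    restrict_ids: list[str] | None = None,
) -> list[GeneVariantSet]:
    """Qualifying per-gene variant sets for the gene-level tests.

    Filters to non-synonymous variants with in-sample MAF strictly below
    ``maf_max`` and keeps genes with at least two such sites. Individuals
    with any missing genotype across a gene's qualifying sites are dropped
    for that gene (complete-case per gene).
    """
    from .simulate import sample_maf

    var = G.variants.copy()
    if annotations is not None:
        ann = annotations.set_index("variant_id")
        missing = [v for v in var["variant_id"] if v not in ann.index]
        if missing:
            raise ValueError(f"variants lacking annotation: {missing[:5]}")
        var["gene"] = ann.loc[var["variant_id"], "gene"].to_numpy()
        var["consequence"] = ann.loc[var["variant_id"], "consequence"].to_numpy()
    maf = sample_maf(G.dosages)
    qualifying = (
        var["consequence"].isin(NONSYNONYMOUS).to_numpy()
        & (maf > 0)
        & (maf < maf_max)
    )
    row_mask = np.ones(G.n_individuals, dtype=bool)
    if restrict_ids is not None:
        keep = set(restrict_ids)
        row_mask = np.array([s in keep for s in G.individuals])

    sets = []
    for gene, grp in var.groupby("gene", sort=True):
        idx = [j for j in grp.index if qualifying[j]]
        if len(idx) < MIN_VARIANTS:
            continue
        sub = G.dosages[np.ix_(row_mask, idx)]
        complete = (sub != MISSING).all(axis=1)
        geno = sub[complete].astype(np.int8)
        inds = [s for s, r, c in zip(
            G.individuals, row_mask, _expand(complete, row_mask)) if r and c]
        sets.append(
            GeneVariantSet(
                gene=str(gene),
                variant_ids=[var.at[j, "variant_id"] for j in idx],
                genotypes=geno,
                individuals=inds,
                mafs=sample_maf(geno),
            )
        )
    return sets


def _expand(complete: np.ndarray, row_mask: np.ndarray) -> np.ndarray:
    out = np.zeros(row_mask.size, dtype=bool)
    out[np.flatnonzero(row_mask)] = complete
    return out


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

def madsen_browning_weights(genotypes: np.ndarray) -> np.ndarray:
    """Inverse-SD burden weights w_j = 1 / sqrt(n p_j (1 - p_j))."""
    n = genotypes.shape[0]
    p = genotypes.mean(axis=0) / 2.0
    p = np.clip(p, 1.0 / (2 * n + 2), 1 - 1.0 / (2 * n + 2))
    return 1.0 / np.sqrt(n * p * (1 - p))


def beta_maf_weights(mafs: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta(1,25)-density variant weights, up-weighting the rarest sites."""
    return stats.beta.pdf(np.clip(mafs, 1e-8, 1 - 1e-8), a, b)


# ---------------------------------------------------------------------------
# CMC burden test
# ---------------------------------------------------------------------------

def _align(
    gs: GeneVariantSet, residuals: pd.Series, pcs
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Intersect the gene set's complete-case individuals with residuals.

    ``pcs`` may be an array aligned row-for-row with ``gs.individuals`` or a
    DataFrame indexed by individual id (cohort-wide scores).
    """
    have = residuals.index
    keep = np.array([s in have for s in gs.individuals])
    kept_ids = np.asarray(gs.individuals, dtype=object)[keep]
    y = residuals.loc[kept_ids].to_numpy(float)
    geno = gs.genotypes[keep].astype(float)
    pc = None
    if pcs is not None:
        if isinstance(pcs, pd.DataFrame):
            pc = pcs.loc[kept_ids].to_numpy(float)
        else:
            pc = np.asarray(pcs, float)[keep]
    return y, geno, pc


def cmc_test(
    gs: GeneVariantSet,
    residuals: pd.Series,
    pcs: np.ndarray | None = None,
    B: int = 10_000,
    seed: int = 0,
    weights: str = "madsen-browning",
    escalate_to: int = 1_000_000,
) -> tuple[float, float, int]:
    """Weighted-sum burden test with permutation p-value.

    Returns ``(stat, p, B_used)`` where ``stat`` is the squared t statistic
    of the burden coefficient in an OLS of the residuals on the burden score
    plus PCs, and ``p = (1 + #{perm stat >= observed}) / (1 + B)``. When the
    estimate hits the resolution floor (p < 10/B) the permutation count is
    escalated tenfold up to ``escalate_to``.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    y, geno, pc = _align(gs, residuals, pcs)
    n = y.size
    if weights == "madsen-browning":
        w = madsen_browning_weights(geno)
    elif weights == "flat":
        w = np.ones(geno.shape[1])
    elif weights == "collapse":
        w = None
    else:
        raise ValueError(f"unknown CMC weight scheme {weights!r}")
    burden = (geno >= 1).any(axis=1).astype(float) if w is None else geno @ w
    if burden.std() == 0:
        return 0.0, 1.0, B

    # covariate block Z = [1, PCs]; orthonormalize once, then each
    # permutation's statistic is a pair of inner products
    Z = np.ones((n, 1)) if pc is None else np.column_stack([np.ones(n), pc])
    Qz, _ = np.linalg.qr(Z)
    b_t = burden - Qz @ (Qz.T @ burden)
    b_norm = np.linalg.norm(b_t)
    if b_norm == 0:
        return 0.0, 1.0, B
    b_u = b_t / b_norm
    k = Z.shape[1] + 1
    df = n - k

    def stat_of(ys: np.ndarray) -> np.ndarray:
        # ys: (n, B) columns of (permuted) phenotype residual vectors
        proj = Qz.T @ ys
        yy = np.einsum("ij,ij->j", ys, ys) - np.einsum("ij,ij->j", proj, proj)
        u = b_u @ ys
        denom = yy - u**2
        denom = np.maximum(denom, 1e-300)
        return df * u**2 / denom

    observed = float(stat_of(y[:, None])[0])
    rng = np.random.default_rng(seed)
    B_used = B
    while True:
        exceed = 0
        done = 0
        chunk = min(B_used, 2_000)
        while done < B_used:
            nb = min(chunk, B_used - done)
            idx = np.argsort(rng.random((nb, n)), axis=1)
            perms = y[idx].T  # (n, nb)
            exceed += int((stat_of(perms) >= observed).sum())
            done += nb
        p = (1 + exceed) / (1 + B_used)
        if p >= 10.0 / B_used or B_used >= escalate_to:
            break
        B_used = min(B_used * 10, escalate_to)
    return observed, p, B_used


# ---------------------------------------------------------------------------
# SKAT
# ---------------------------------------------------------------------------

def imhof_pvalue(q: float, lambdas: np.ndarray) -> float:
    """P(sum_k lambda_k chi2_1 >= q) by Imhof's inversion integral."""
    lam = np.asarray(lambdas, float)
    lam = lam[np.abs(lam) > 1e-12 * max(np.abs(lam).max(), 1.0)]
    if lam.size == 0:
        return 1.0
    if np.allclose(lam, lam[0], rtol=1e-12):
        # equal weights: the mixture is an exact (scaled) chi-square
        return float(stats.chi2.sf(q / lam[0], lam.size))

    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        rho = np.exp(0.25 * np.sum(np.log1p((lam * u) ** 2)))
        return np.sin(theta) / (u * rho)

    # full_output=1 suppresses the slow-convergence warning from the
    # oscillatory tail; accuracy is still ~1e-6 absolute, ample for the
    # p-value scales at which the asymptotic route is used
    out = integrate.quad(
        integrand, 0, np.inf, limit=500, epsabs=1e-12, epsrel=1e-10, full_output=1
    )
    p = 0.5 + out[0] / np.pi
    return float(min(max(p, 1e-16), 1.0))


def liu_pvalue(q: float, lambdas: np.ndarray) -> float:
    """Moment-matched chi-square approximation to the mixture tail."""
    lam = np.asarray(lambdas, float)
    c1, c2, c3, c4 = (np.sum(lam**k) for k in (1, 2, 3, 4))
    if c2 <= 0:
        return 1.0
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    mu_q = c1
    sigma_q = np.sqrt(2 * c2)
    t_star = (q - mu_q) / sigma_q
    if s1**2 > s2:
        a = 1 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        delta = 0.0
        df = 1 / s2 if s2 > 0 else 1.0
    mu_x = df + delta
    sigma_x = np.sqrt(2 * (df + 2 * delta))
    p = stats.ncx2.sf(t_star * sigma_x + mu_x, df, delta)
    return float(min(max(p, 1e-16), 1.0))


def mixture_pvalue(q: float, lambdas: np.ndarray) -> float:
    """Imhof inversion with Liu fallback on numerical failure."""
    try:
        with np.errstate(all="ignore"):
            p = imhof_pvalue(q, lambdas)
        if not np.isfinite(p) or p <= 0:
            raise FloatingPointError
        # inversion loses accuracy deep in the tail; hand off to Liu there
        if p < 1e-12:
            return liu_pvalue(q, lambdas)
        return p
    except Exception:
        return liu_pvalue(q, lambdas)


def skat_test(
    gs: GeneVariantSet,
    residuals: pd.Series,
    pcs: np.ndarray | None = None,
    weights: str = "beta",
) -> tuple[float, float]:
    """SKAT variance-component score test with asymptotic p-value.

    Returns ``(Q, p)``. The null model regresses the phenotype residuals on
    the PCs (plus intercept); Q = r' G W^2 G' r with r the null-model
    residuals, and the reference distribution is sigma^2 times the
    eigenvalue-weighted chi-square mixture of W G' P G W.
    """
    y, geno, pc = _align(gs, residuals, pcs)
    n = y.size
    if weights == "beta":
        w = beta_maf_weights(geno.mean(axis=0) / 2.0)
    elif weights == "flat":
        w = np.ones(geno.shape[1])
    else:
        raise ValueError(f"unknown SKAT weight scheme {weights!r}")
    Z = np.ones((n, 1)) if pc is None else np.column_stack([np.ones(n), pc])
    Qz, _ = np.linalg.qr(Z)
    r = y - Qz @ (Qz.T @ y)
    sigma2 = float(r @ r) / (n - Z.shape[1])
    if sigma2 == 0:
        return 0.0, 1.0
    K = geno * w  # G W, (n, m)
    A = K - Qz @ (Qz.T @ K)  # P G W
    score = A.T @ r
    Q = float(score @ score)
    lam = np.linalg.eigvalsh(A.T @ A)
    lam = lam[lam > 1e-10 * max(lam.max(), 1.0)] if lam.size else lam
    if lam.size == 0:
        return Q, 1.0
    p = mixture_pvalue(Q / sigma2, lam)
    return Q, p


def skat_permutation_pvalues(
    gs: GeneVariantSet,
    residuals: pd.Series,
    pcs: np.ndarray | None = None,
    B: int = 2_000,
    seed: int = 0,
    weights: str = "beta",
) -> float:
    """Permutation p-value for SKAT's Q (calibration cross-check path)."""
    y, geno, pc = _align(gs, residuals, pcs)
    n = y.size
    if weights == "beta":
        w = beta_maf_weights(geno.mean(axis=0) / 2.0)
    else:
        w = np.ones(geno.shape[1])
    Z = np.ones((n, 1)) if pc is None else np.column_stack([np.ones(n), pc])
    Qz, _ = np.linalg.qr(Z)
    K = geno * w
    A = K - Qz @ (Qz.T @ K)
    r = y - Qz @ (Qz.T @ y)
    q_obs = float(np.sum((A.T @ r) ** 2))
    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    while done < B:
        nb = min(2_000, B - done)
        idx = np.argsort(rng.random((nb, n)), axis=1)
        Y = y[idx].T  # (n, nb)
        R = Y - Qz @ (Qz.T @ Y)
        qs = np.sum((A.T @ R) ** 2, axis=0)
        exceed += int((qs >= q_obs).sum())
        done += nb
    return (1 + exceed) / (1 + B)


# ---------------------------------------------------------------------------
# direction summary and driver
# ---------------------------------------------------------------------------

def direction_summary(gs: GeneVariantSet, residuals: pd.Series) -> tuple[int, int]:
    """Count variants whose carriers' mean residual is above/below others."""
    y, geno, _ = _align(gs, residuals, None)
    up = down = 0
    for j in range(geno.shape[1]):
        carriers = geno[:, j] >= 1
        if not carriers.any() or carriers.all():
            continue
        if y[carriers].mean() > y[~carriers].mean():
            up += 1
        else:
            down += 1
    return up, down


def gene_level_scan(
    gene_sets: list[GeneVariantSet],
    residuals: pd.Series,
    trait: str,
    pcs: np.ndarray | None = None,
    B: int = 10_000,
    seed: int = 0,
) -> list[GeneTestResult]:
    """Run CMC and SKAT for every gene set against one trait's residuals."""
    results = []
    for g_i, gs in enumerate(gene_sets):
        stat, cmc_p, b_used = cmc_test(
            gs, residuals, pcs=pcs, B=B, seed=seed + g_i
        )
        Q, skat_p = skat_test(gs, residuals, pcs=pcs)
        up, down = direction_summary(gs, residuals)
        y, _, _ = _align(gs, residuals, None)
        results.append(
            GeneTestResult(
                gene=gs.gene, trait=trait, n=y.size, n_variants=gs.n_variants,
                cmc_stat=stat, cmc_p=cmc_p, cmc_B=b_used,
                skat_Q=Q, skat_p=skat_p, n_up=up, n_down=down,
            )
        )
    return results
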