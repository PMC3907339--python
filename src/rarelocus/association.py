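"""Phenotype residualization, genotype PCA, and single-variant tests.

Residuals are formed once per trait (log transform where appropriate, then
ordinary least squares on demographic covariates over the combined cohorts)
and reused by every downstream test; stratification is controlled by adding
the top genotype principal components as covariates. Conditional tests add
the locus's array-SNP dosage to the covariates to ask whether a signal is
independent of the known common association.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .containers import LOG_TRAITS, MISSING, TRAITS, GenotypeMatrix

LD_INDEPENDENT_R2 = 0.20
COLLINEAR_R2 = 0.99
MAF_MIN_SINGLE = 0.001
MAF_MIN_CASE_CONTROL = 0.01


# ---------------------------------------------------------------------------
# small dense OLS helper (exact t p-values; used by every regression scan)
# ---------------------------------------------------------------------------

def ols_fit(X: np.ndarray, y: np.ndarray):
    """OLS of y on X (X includes any intercept column).

    Returns (beta, se, t, p, rss, df_resid). Uses the pseudoinverse-free
    lstsq path; raises LinAlgError-like ValueError on deficient rank so
    callers can flag collinearity.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, k = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - k
    xtx_inv = np.linalg.inv(X.T @ X)
    sigma2 = rss / df
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, t, p, rss, df


# ---------------------------------------------------------------------------
# residualization
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeResiduals:
    trait: str
    residuals: pd.Series  # indexed by individual id; excluded ids absent
    transformation: str  # "log" | "inverse-normal" | "none"
    covariates: list[str]
    excluded: pd.DataFrame  # id, reason
    coefficients: dict[str, float] = field(default_factory=dict)


def _covariate_design(ph: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    age_c = ph["age"].to_numpy(float) - 45.0
    cols = {
        "intercept": np.ones(len(ph)),
        "age": age_c,
        "age2": age_c**2,
        "sex": ph["sex"].to_numpy(float),
        "oc_use": ph["oc_use"].to_numpy(float),
        "pregnant": ph["pregnant"].to_numpy(float),
        "cohort": ph["cohort"].astype(str).str.startswith("cohortB").to_numpy(float),
    }
    # constant indicator columns (e.g. nobody pregnant in a small sample)
    # carry no information and would make the design singular
    cols = {
        name: v for name, v in cols.items()
        if name == "intercept" or np.std(v) > 0
    }
    return np.column_stack(list(cols.values())), list(cols)


def inverse_normal(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform (Blom offsets)."""
    r = stats.rankdata(x)
    return stats.norm.ppf((r - 0.375) / (len(x) + 0.25))


def residualize(
    phenotypes: pd.DataFrame, trait: str, transform: str | None = None
) -> PhenotypeResiduals:
    """Combined-cohort covariate adjustment for one trait.

    TG, FG and FI are log-transformed before adjustment (``transform``
    overrides: "none", "log", or "inverse-normal" applied to the residuals).
    Type-2-diabetes cases are excluded from the glycemic traits FG and FI.
    """
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}")
    ph = phenotypes.copy()
    excluded = []
    if trait in ("FG", "FI"):
        mask = ph["case_status"].to_numpy() == 1
        for i in ph.loc[mask, "id"]:
            excluded.append((i, "T2D-case"))
        ph = ph.loc[~mask]
    nan_mask = ph[trait].isna().to_numpy()
    for i in ph.loc[nan_mask, "id"]:
        excluded.append((i, "missing-phenotype"))
    ph = ph.loc[~nan_mask]

    y = ph[trait].to_numpy(float)
    use_log = (trait in LOG_TRAITS) if transform is None else transform == "log"
    applied = "none"
    if use_log:
        bad = y <= 0
        if bad.any():
            raise ValueError(
                f"log transform of {trait}: non-positive values for individuals "
                f"{list(ph.loc[bad, 'id'])[:10]}"
            )
        y = np.log(y)
        applied = "log"
    X, names = _covariate_design(ph)
    beta, *_ = ols_fit(X, y)
    resid = y - X @ beta
    if transform == "inverse-normal":
        resid = inverse_normal(resid)
        applied = "inverse-normal"
    return PhenotypeResiduals(
        trait=trait,
        residuals=pd.Series(resid, index=ph["id"].astype(str).to_numpy()),
        transformation=applied,
        covariates=names,
        excluded=pd.DataFrame(excluded, columns=["id", "reason"]),
        coefficients=dict(zip(names, map(float, beta))),
    )


# ---------------------------------------------------------------------------
# LD pruning and genotype PCA
# ---------------------------------------------------------------------------

def ld_r2(a: np.ndarray, b: np.ndarray, min_overlap: int = 30) -> float:
    """Squared Pearson correlation of two dosage vectors (complete pairs)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < min_overlap:
        raise ValueError(f"fewer than {min_overlap} overlapping non-missing pairs")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def independence_check(r2: float) -> bool:
    """Two variants are treated as independent signals iff r^2 < 0.20."""
    return bool(r2 < LD_INDEPENDENT_R2)


def ld_prune(
    G: GenotypeMatrix,
    r2_max: float = 0.5,
    window: int = 50,
    step: int = 5,
    maf_min: float = 0.01,
) -> list[int]:
    """Greedy left-to-right pruning: indices of retained common SNPs.

    Within a sliding window of ``window`` SNPs (advanced by ``step``), a SNP
    is dropped when its r^2 with any already-retained SNP in the window
    reaches ``r2_max``.
    """
    from .simulate import sample_maf

    maf = sample_maf(G.dosages)
    candidates = [j for j in range(G.n_variants) if maf[j] >= maf_min]
    removed: set[int] = set()
    for start in range(0, max(len(candidates), 1), step):
        win = candidates[start : start + window]
        if not win:
            break
        for ai in range(len(win)):
            if win[ai] in removed:
                continue
            for bi in range(ai + 1, len(win)):
                if win[bi] in removed:
                    continue
                try:
                    r2 = ld_r2(G.dosages[:, win[ai]], G.dosages[:, win[bi]], min_overlap=2)
                except ValueError:
                    continue
                if np.isfinite(r2) and r2 >= r2_max:
                    removed.add(win[bi])
    return [j for j in candidates if j not in removed]


@dataclass
class PCSet:
    scores: np.ndarray  # (n_individuals, K)
    eigenvalues: np.ndarray
    snp_indices: list[int]


def genotype_pca(G: GenotypeMatrix, snp_indices: list[int] | None = None, K: int = 5) -> PCSet:
    """PCA of genotypes standardized per SNP by 2p and sqrt(p(1-p)).

    Missing dosages are mean-imputed (zero after centering), the standard
    convention for genotype PCA.
    """
    from .simulate import sample_maf

    if snp_indices is None:
        snp_indices = list(range(G.n_variants))
    X = G.dosages[:, snp_indices].astype(float)
    X[X == MISSING] = np.nan
    p = np.nanmean(X, axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    X = X[:, keep]
    p = p[keep]
    X = (X - 2 * p) / np.sqrt(p * (1 - p))
    X = np.nan_to_num(X, nan=0.0)
    if K > min(X.shape):
        raise ValueError(f"K={K} exceeds the rank bound {min(X.shape)}")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    n = X.shape[0]
    return PCSet(
        scores=U[:, :K] * s[:K],
        eigenvalues=(s[:K] ** 2) / (n - 1),
        snp_indices=[j for j, k in zip(snp_indices, keep) if k],
    )


# ---------------------------------------------------------------------------
# single-variant tests
# ---------------------------------------------------------------------------

@dataclass
class SingleVariantResult:
    variant_id: str
    trait: str
    model: str
    beta: float
    se: float
    p: float
    maf: float
    n: int
    conditioned_on: list[str] = field(default_factory=list)
    flag: str = ""


def _code_genotype(d: np.ndarray, model: str) -> np.ndarray:
    if model == "additive":
        return d.astype(float)
    if model == "dominant":
        return (d >= 1).astype(float)
    if model == "recessive":
        return (d == 2).astype(float)
    raise ValueError(f"unknown genetic model {model!r}")


def single_variant_test(
    residuals: pd.Series,
    dosages: np.ndarray,
    individuals: list[str],
    pcs: np.ndarray | None = None,
    model: str = "additive",
    variant_id: str = "",
    trait: str = "",
    extra_covariates: np.ndarray | None = None,
    conditioned_on: list[str] | None = None,
    maf_min: float = MAF_MIN_SINGLE,
) -> SingleVariantResult:
    """OLS of phenotype residuals on coded dosage (+ PCs), two-sided t test.

    Individuals missing the dosage or absent from the residual set are
    dropped per variant (complete-case); sites monomorphic after that, or
    below the MAF floor, are skipped with a flag.
    """
    ids = np.asarray(individuals, dtype=object)
    res_index = residuals.index
    in_res = pd.Index(ids).isin(res_index)
    dos = np.asarray(dosages)
    use = in_res & (dos != MISSING)
    dos_u = dos[use].astype(float)
    y = residuals.loc[ids[use]].to_numpy(float)
    n = int(use.sum())
    mac = min(dos_u.sum(), 2 * n - dos_u.sum()) if n else 0
    maf = mac / (2 * n) if n else float("nan")

    def _skip(flag: str) -> SingleVariantResult:
        return SingleVariantResult(
            variant_id, trait, model, float("nan"), float("nan"), float("nan"),
            maf, n, list(conditioned_on or []), flag,
        )

    if n < 3 or len(np.unique(dos_u)) < 2:
        return _skip("monomorphic")
    if maf <= maf_min:
        return _skip("below-maf-floor")

    g = _code_genotype(dos_u, model)
    cols = [np.ones(n), g]
    if pcs is not None:
        cols.append(np.asarray(pcs)[use])
    if extra_covariates is not None:
        extra = np.asarray(extra_covariates, float)
        if extra.ndim == 1:
            extra = extra[:, None]
        extra = extra[use]
        informative = []
        for c in extra.T:
            if np.std(c) == 0:
                continue  # constant covariate carries no information
            r2 = np.corrcoef(g, c)[0, 1] ** 2 if np.std(g) > 0 else 1.0
            if r2 > COLLINEAR_R2:
                return _skip("collinear-with-covariate")
            informative.append(c)
        if informative:
            cols.append(np.column_stack(informative))
    X = np.column_stack(cols)
    try:
        beta, se, _, p, _, _ = ols_fit(X, y)
    except np.linalg.LinAlgError:
        return _skip("non-estimable")
    return SingleVariantResult(
        variant_id, trait, model, float(beta[1]), float(se[1]), float(p[1]),
        maf, n, list(conditioned_on or []), "",
    )


def conditional_test(
    residuals: pd.Series,
    dosages: np.ndarray,
    array_dosages: np.ndarray,
    individuals: list[str],
    pcs: np.ndarray | None = None,
    model: str = "additive",
    variant_id: str = "",
    trait: str = "",
    array_id: str = "array_snp",
) -> SingleVariantResult:
    """Single-variant test with the array-SNP dosage added as a covariate."""
    arr = np.asarray(array_dosages, float)
    arr = np.where(arr == MISSING, np.nanmean(np.where(arr == MISSING, np.nan, arr)), arr)
    return single_variant_test(
        residuals, dosages, individuals, pcs=pcs, model=model,
        variant_id=variant_id, trait=trait,
        extra_covariates=arr, conditioned_on=[array_id],
    )


def select_array_snp(results: list[SingleVariantResult]) -> str:
    """Smallest-p array SNP at a locus; ties broken by position then id.

    ``results`` must carry variant ids of the form ``gene:chrom:pos`` (the
    simulator's convention) or anything sortable as a final tie-break.
    """
    usable = [r for r in results if np.isfinite(r.p)]
    if not usable:
        raise ValueError("no testable array SNP at this locus")

    def _pos(r: SingleVariantResult):
        parts = r.variant_id.rsplit(":", 1)
        try:
            return int(parts[-1])
        except ValueError:
            return 0

    return min(usable, key=lambda r: (r.p, _pos(r), r.variant_id)).variant_id


def case_control_test(
    case_labels: np.ndarray,
    dosages: np.ndarray,
    pcs: np.ndarray | None = None,
    variant_id: str = "",
    maf_min: float = MAF_MIN_CASE_CONTROL,
) -> SingleVariantResult:
    """Logistic regression Wald test of case status on additive dosage.

    Beta is on the log-odds scale. Perfect-separation / non-convergence is
    reported via the ``quasi-separation`` flag rather than raised.
    """
    labels = np.asarray(case_labels, int)
    dos = np.asarray(dosages)
    use = dos != MISSING
    dos_u = dos[use].astype(float)
    y = labels[use]
    n = int(use.sum())
    mac = min(dos_u.sum(), 2 * n - dos_u.sum()) if n else 0
    maf = mac / (2 * n) if n else float("nan")

    def _skip(flag: str) -> SingleVariantResult:
        return SingleVariantResult(
            variant_id, "T2D", "logistic-additive", float("nan"), float("nan"),
            float("nan"), maf, n, [], flag,
        )

    if len(np.unique(dos_u)) < 2 or len(np.unique(y)) < 2:
        return _skip("monomorphic")
    if maf <= maf_min:
        return _skip("below-maf-floor")
    cols = [np.ones(n), dos_u]
    if pcs is not None:
        cols.append(np.asarray(pcs)[use])
    X = np.column_stack(cols)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        if not fit.mle_retvals.get("converged", True):
            return _skip("quasi-separation")
    except Exception:
        return _skip("quasi-separation")
    return SingleVariantResult(
        variant_id, "T2D", "logistic-additive",
        float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1]),
        maf, n, [], "",
    )
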