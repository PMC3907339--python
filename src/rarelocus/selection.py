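"""Greedy BIC multivariate model selection and variance-explained accounting.

The search starts from a base model holding the intercept and the top
principal components, and repeatedly applies whichever single move — adding
one candidate variant or dropping one already-selected variant — most
decreases BIC = n ln(RSS/n) + k ln(n), stopping when no move decreases it.
Singleton variants are excluded from candidacy (one observation supports no
inference about their effect).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix
from .association import ols_fit


@dataclass
class SelectionResult:
    locus: str
    trait: str
    selected: list[str]
    betas: dict[str, float]
    ses: dict[str, float]
    pvalues: dict[str, float]
    bic_trace: list[float]  # BIC after each accepted move, starting at base
    n: int
    excluded_singletons: list[str] = field(default_factory=list)


def bic(rss: float, n: int, k: int) -> float:
    """BIC with Gaussian likelihood; k counts every free coefficient."""
    return n * np.log(rss / n) + k * np.log(n)


def _rss(X: np.ndarray, y: np.ndarray) -> float | None:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        return None  # singular move, skip
    r = y - X @ beta
    return float(r @ r)


def greedy_bic_select(
    residuals: pd.Series,
    G_locus: GenotypeMatrix,
    pcs: np.ndarray | None = None,
    locus: str = "",
    trait: str = "",
    exclude_singletons: bool = True,
) -> SelectionResult:
    """Bidirectional stepwise BIC search over a locus's candidate variants.

    Only complete observations (no missing dosage at any candidate, residual
    available) enter. Exact BIC ties between moves are broken by genomic
    position, then variant id, for determinism.
    """
    ids = np.asarray(G_locus.individuals, dtype=object)
    in_res = pd.Index(ids).isin(residuals.index)
    complete = (G_locus.dosages != MISSING).all(axis=1)
    use = in_res & complete
    y = residuals.loc[ids[use]].to_numpy(float)
    n = int(use.sum())
    dos = G_locus.dosages[use].astype(float)

    var = G_locus.variants
    mac = np.minimum(dos.sum(0), 2 * n - dos.sum(0))
    singles = mac == 1
    poly = mac >= 1
    candidates = [
        j for j in range(G_locus.n_variants)
        if poly[j] and not (exclude_singletons and singles[j])
    ]
    excluded = [var.at[j, "variant_id"] for j in range(G_locus.n_variants)
                if exclude_singletons and singles[j]]

    base_cols = [np.ones(n)]
    if pcs is not None:
        base_cols.append(np.asarray(pcs, float)[use])
    Zbase = np.column_stack(base_cols)
    k_base = Zbase.shape[1]

    def design(sel: list[int]) -> np.ndarray:
        if not sel:
            return Zbase
        return np.column_stack([Zbase, dos[:, sel]])

    def tie_key(j: int):
        return (int(var.at[j, "pos"]), str(var.at[j, "variant_id"]))

    rss0 = _rss(Zbase, y)
    if rss0 is None:
        raise np.linalg.LinAlgError("base covariate design is singular")
    current_bic = bic(rss0, n, k_base)
    trace = [current_bic]
    selected: list[int] = []

    while True:
        moves = []  # (bic, tiebreak, kind, j)
        for j in candidates:
            if j in selected:
                continue
            rss = _rss(design(selected + [j]), y)
            if rss is None or rss <= 0:
                continue
            moves.append((bic(rss, n, k_base + len(selected) + 1), tie_key(j), "add", j))
        for j in selected:
            rest = [s for s in selected if s != j]
            rss = _rss(design(rest), y)
            if rss is None or rss <= 0:
                continue
            moves.append((bic(rss, n, k_base + len(rest)), tie_key(j), "drop", j))
        if not moves:
            break
        best = min(moves, key=lambda m: (m[0], m[1]))
        if best[0] >= current_bic - 1e-9:
            break
        current_bic = best[0]
        trace.append(current_bic)
        if best[2] == "add":
            selected.append(best[3])
        else:
            selected.remove(best[3])

    betas: dict[str, float] = {}
    ses: dict[str, float] = {}
    ps: dict[str, float] = {}
    if selected:
        X = design(selected)
        b, se, _, p, _, _ = ols_fit(X, y)
        for col, j in enumerate(selected, start=k_base):
            vid = var.at[j, "variant_id"]
            betas[vid] = float(b[col])
            ses[vid] = float(se[col])
            ps[vid] = float(p[col])
    order = sorted(selected, key=tie_key)
    return SelectionResult(
        locus=locus, trait=trait,
        selected=[var.at[j, "variant_id"] for j in order],
        betas=betas, ses=ses, pvalues=ps,
        bic_trace=trace, n=n, excluded_singletons=excluded,
    )


def variance_explained(
    residuals: pd.Series,
    G: GenotypeMatrix,
    model_variants: list[str],
    array_snp: str,
    pcs: np.ndarray | None = None,
) -> tuple[float, float]:
    """Percent phenotype variance from the array SNP alone vs the full model.

    Both R^2 values are computed on PC-partialled data (the PCs are removed
    from the phenotype and from every genotype column first), so the
    reported percentages isolate the genetic contribution. The full model
    holds the array SNP plus the selected sequence variants; by nesting,
    R2_full >= R2_array.
    """
    wanted = [array_snp] + [v for v in model_variants if v != array_snp]
    ids = np.asarray(G.individuals, dtype=object)
    in_res = pd.Index(ids).isin(residuals.index)
    cols = np.column_stack([G.column(v) for v in wanted]).astype(float)
    complete = (cols != MISSING).all(axis=1)
    use = in_res & complete
    y = residuals.loc[ids[use]].to_numpy(float)
    X = cols[use]
    n = y.size

    Z = np.ones((n, 1)) if pcs is None else np.column_stack(
        [np.ones(n), np.asarray(pcs, float)[use]]
    )
    Qz, _ = np.linalg.qr(Z)
    y_t = y - Qz @ (Qz.T @ y)
    X_t = X - Qz @ (Qz.T @ X)
    tss = float(y_t @ y_t)
    if tss == 0:
        return 0.0, 0.0

    def r2(cols_t: np.ndarray) -> float:
        beta, _, _, _ = np.linalg.lstsq(cols_t, y_t, rcond=None)
        resid = y_t - cols_t @ beta
        return 1.0 - float(resid @ resid) / tss

    r2_array = r2(X_t[:, :1])
    r2_full = r2(X_t)
    return 100.0 * r2_array, 100.0 * r2_full
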