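"""Multiple-testing thresholds and locus-phenotype report assembly.

Single-variant and gene-level p-values are pooled into one family. The
operating rule mirrors the reference analysis: a fixed p < 0.001 cutoff by
default (approximately FDR 0.02 on the study's test inventory), with
Benjamini-Hochberg and Bonferroni cutoffs available explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import LD_INDEPENDENT_R2, SingleVariantResult

FIXED_THRESHOLD = 0.001


@dataclass
class TestInventory:
    """Pooled family of tests: (id, family, locus, trait, p)."""

    __test__ = False  # not a pytest class, despite the domain name

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"test_id", "family", "locus", "trait", "p"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"inventory lacks columns {sorted(missing)}")
        if self.table["test_id"].duplicated().any():
            raise ValueError("test ids must be unique")
        p = self.table["p"].to_numpy(float)
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("p-values must lie in (0, 1]")


@dataclass
class ThresholdResult:
    method: str
    level: float
    m: int
    cutoff: float
    significant: list[str] = field(default_factory=list)


def bh_threshold(p_values, q: float = 0.05, test_ids=None) -> ThresholdResult:
    """Benjamini-Hochberg step-up cutoff at FDR level ``q``.

    cutoff = p_(k*) for the largest k with p_(k) <= k q / m; 0 when no
    rejection. (Cross-checked in the tests against the statsmodels
    implementation.)
    """
    p = np.asarray(p_values, float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    ok = sorted_p <= (np.arange(1, m + 1) * q / m)
    if not ok.any():
        cutoff = 0.0
    else:
        cutoff = float(sorted_p[np.flatnonzero(ok)[-1]])
    sig_mask = p <= cutoff if cutoff > 0 else np.zeros(m, bool)
    ids = list(np.asarray(test_ids)[sig_mask]) if test_ids is not None else [
        str(i) for i in np.flatnonzero(sig_mask)
    ]
    return ThresholdResult("BH", q, m, cutoff, ids)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Plain alpha/m cutoff (report formatting rounds to 2 s.f.)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def format_2sf(x: float) -> str:
    """Two-significant-figure scientific formatting used in the reports."""
    return f"{x:.1e}"


REPORT_COLUMNS = [
    "locus", "trait", "variant_id", "role", "maf", "beta", "se", "p",
    "consequence", "r2_with_array", "pv_array_pct", "pv_full_pct",
]


def build_report(
    array_results: dict[tuple[str, str], SingleVariantResult],
    conditional_results: dict[tuple[str, str], list[SingleVariantResult]],
    annotations: pd.DataFrame,
    r2_with_array: dict[tuple[str, str, str], float],
    variance: dict[tuple[str, str], tuple[float, float]] | None = None,
    threshold: float = FIXED_THRESHOLD,
) -> pd.DataFrame:
    """Assemble the locus-phenotype association report.

    One row for each locus-trait array SNP, plus a row per sequence variant
    whose conditional p-value clears ``threshold`` and whose r^2 with the
    array SNP is below the independence bound (0.20).

    Parameters
    ----------
    array_results
        (locus, trait) -> array-SNP single-variant result.
    conditional_results
        (locus, trait) -> conditional results for the locus's other variants.
    annotations
        variant_id -> consequence lookup table.
    r2_with_array
        (locus, trait, variant_id) -> LD with the array SNP.
    variance
        optional (locus, trait) -> (R2_array %, R2_full %).
    """
    if not array_results:
        raise ValueError("missing upstream outputs: single-variant stage is empty")
    ann = annotations.set_index("variant_id")["consequence"]
    rows = []
    for (locus, trait), arr in sorted(array_results.items()):
        pv = (variance or {}).get((locus, trait), (np.nan, np.nan))
        rows.append({
            "locus": locus, "trait": trait, "variant_id": arr.variant_id,
            "role": "array", "maf": arr.maf, "beta": arr.beta, "se": arr.se,
            "p": arr.p, "consequence": ann.get(arr.variant_id, "array"),
            "r2_with_array": 1.0,
            "pv_array_pct": pv[0], "pv_full_pct": pv[1],
        })
        for r in conditional_results.get((locus, trait), []):
            if not np.isfinite(r.p) or r.p >= threshold:
                continue
            r2 = r2_with_array.get((locus, trait, r.variant_id), np.nan)
            if not (np.isfinite(r2) and r2 < LD_INDEPENDENT_R2):
                continue
            rows.append({
                "locus": locus, "trait": trait, "variant_id": r.variant_id,
                "role": "independent", "maf": r.maf, "beta": r.beta,
                "se": r.se, "p": r.p,
                "consequence": ann.get(r.variant_id, ""),
                "r2_with_array": r2,
                "pv_array_pct": pv[0], "pv_full_pct": pv[1],
            })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
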