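"""Consensus merging of replicate call sets, sample QC, validation ledger.

The consensus rule is 2-of-3 majority over genotype values: sites whose ALT
alleles disagree between centers (or are multi-allelic) are excluded
outright; at retained sites a genotype enters the consensus only when at
least two centers call the same value, and is missing otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, CenterCallSet, GenotypeMatrix

GENOTYPE_CLASSES = {0: "hom_ref", 1: "het", 2: "hom_alt"}


@dataclass
class ConsensusResult:
    consensus: GenotypeMatrix
    #: per-site exclusion reason: none | multi-allelic | alt-mismatch
    site_exclusions: pd.DataFrame
    #: True where all three centers called but no two agreed
    discordant_missing: np.ndarray
    concordance_overall: float
    concordance_by_class: dict[str, float]


def _check_alignment(callsets: list[CenterCallSet]) -> None:
    ref = callsets[0]
    for cs in callsets[1:]:
        if list(cs.individuals) != list(ref.individuals):
            a, b = set(ref.individuals), set(cs.individuals)
            raise ValueError(
                "individual IDs differ between centers "
                f"{ref.center} and {cs.center}: only-in-{ref.center}="
                f"{sorted(a - b)[:5]} only-in-{cs.center}={sorted(b - a)[:5]}"
            )
        if list(cs.variants["variant_id"]) != list(ref.variants["variant_id"]):
            raise ValueError(
                f"variant lists differ between centers {ref.center} and {cs.center}"
            )


def merge_consensus(callsets: list[CenterCallSet]) -> ConsensusResult:
    """Merge >=2 aligned center call sets into a consensus genotype matrix.

    Pairwise concordance is computed over pairs where both centers made a
    call, overall and stratified by genotype class (the class of the
    majority value at that cell, falling back to the first center's call
    when no majority exists).
    """
    if len(callsets) < 2:
        raise ValueError("need at least two center call sets")
    _check_alignment(callsets)

    ref_var = callsets[0].variants.reset_index(drop=True)
    m = len(ref_var)
    reasons = np.array(["none"] * m, dtype=object)
    for cs in callsets:
        multi = cs.variants["alt"].astype(str).str.contains(",").to_numpy()
        reasons[multi & (reasons == "none")] = "multi-allelic"
    alts = np.stack([cs.variants["alt"].astype(str).to_numpy() for cs in callsets])
    mismatch = (alts != alts[0]).any(axis=0)
    reasons[mismatch & (reasons == "none")] = "alt-mismatch"
    keep = reasons == "none"

    stack = np.stack([cs.dosages for cs in callsets])  # (C, n, m)
    counts = np.stack([(stack == g).sum(axis=0) for g in (0, 1, 2)])  # (3, n, m)
    best = counts.argmax(axis=0)
    nbest = np.take_along_axis(counts, best[None], axis=0)[0]
    consensus = np.where(nbest >= 2, best, MISSING).astype(np.int8)
    called = (stack != MISSING).sum(axis=0)
    discordant = (called == len(callsets)) & (nbest < 2)

    # pairwise concordance over non-missing pairs
    n_pairs = 0
    n_agree = 0
    per_class_pairs = {c: 0 for c in GENOTYPE_CLASSES.values()}
    per_class_agree = {c: 0 for c in GENOTYPE_CLASSES.values()}
    cls_value = np.where(nbest >= 2, best, stack[0])  # class label per cell
    for a in range(len(callsets)):
        for b in range(a + 1, len(callsets)):
            da, db = stack[a], stack[b]
            ok = (da != MISSING) & (db != MISSING)
            agree = ok & (da == db)
            n_pairs += int(ok.sum())
            n_agree += int(agree.sum())
            for g, name in GENOTYPE_CLASSES.items():
                sel = ok & (cls_value == g)
                per_class_pairs[name] += int(sel.sum())
                per_class_agree[name] += int((agree & (cls_value == g)).sum())
    overall = n_agree / n_pairs if n_pairs else float("nan")
    by_class = {
        name: (per_class_agree[name] / per_class_pairs[name]
               if per_class_pairs[name] else float("nan"))
        for name in GENOTYPE_CLASSES.values()
    }

    consensus[:, ~keep] = MISSING
    cons_G = GenotypeMatrix(
        consensus[:, keep], list(callsets[0].individuals),
        ref_var.loc[keep].reset_index(drop=True),
    )
    excl = pd.DataFrame({"variant_id": ref_var["variant_id"], "reason": reasons})
    return ConsensusResult(cons_G, excl, discordant[:, keep], overall, by_class)


# ---------------------------------------------------------------------------
# sample-level QC
# ---------------------------------------------------------------------------

COVERAGE_MIN = 0.70
CONCORDANCE_MIN = 0.90


def sample_qc(
    coverage: pd.DataFrame,
    array_check: GenotypeMatrix,
    sequence: GenotypeMatrix,
) -> pd.DataFrame:
    """Per-individual inclusion: >=70% of target at 20x and >=90% genotype
    concordance with the array check SNPs.

    Parameters
    ----------
    coverage
        Columns ``id`` and ``coverage_fraction`` (fraction of target bp at
        >=20x depth, precomputed upstream).
    array_check, sequence
        Genotypes at the check-SNP panel from the array and from sequencing,
        over the same variants; individuals are matched by id.

    Returns a report sorted by individual id with columns
    ``id, coverage_fraction, concordance, pass, reason``.
    """
    if array_check.n_variants == 0:
        raise ValueError("check-SNP set is empty")
    if list(array_check.variant_ids) != list(sequence.variant_ids):
        raise ValueError("array and sequence check-SNP panels differ")
    cov_map = dict(zip(coverage["id"].astype(str), coverage["coverage_fraction"]))
    seq_idx = {s: i for i, s in enumerate(sequence.individuals)}

    rows = []
    for i, ind in enumerate(array_check.individuals):
        cov = cov_map.get(str(ind))
        j = seq_idx.get(ind)
        if cov is None or j is None:
            rows.append((ind, np.nan, np.nan, False, "absent-from-coverage-table"
                         if cov is None else "absent-from-sequence-data"))
            continue
        a = array_check.dosages[i]
        s = sequence.dosages[j]
        ok = (a != MISSING) & (s != MISSING)
        conc = float((a[ok] == s[ok]).mean()) if ok.any() else np.nan
        passed = bool(cov >= COVERAGE_MIN and conc >= CONCORDANCE_MIN)
        reason = "" if passed else ";".join(
            r for r, bad in (
                ("coverage<0.70", cov < COVERAGE_MIN),
                ("concordance<0.90", not conc >= CONCORDANCE_MIN),
            ) if bad
        )
        rows.append((ind, cov, conc, passed, reason))
    report = pd.DataFrame(
        rows, columns=["id", "coverage_fraction", "concordance", "pass", "reason"]
    )
    return report.sort_values("id", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# validation bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class ValidationCounts:
    """Raw inputs to the low-count-variant validation ledger.

    ``attempted`` sites (all variants seen in <=3 individuals and absent
    from the SNP database) stratify into tripletons, doubletons and
    singletons; singleton outcomes split into validated (genomic or
    WGA-only DNA), refuted, not covered, WGA artifact, or reclassified as
    homozygous-alternative.
    """

    initial_sites: int = 0
    attempted: int = 0
    tripleton_sites: int = 0
    tripleton_validated: int = 0
    doubleton_sites: int = 0
    doubleton_validated: int = 0
    singleton_wga_only: int = 0
    singleton_refuted: int = 0
    singleton_not_covered: int = 0
    singleton_wga_artifact: int = 0
    homozygous_alt_reclassified: int = 0
    reincluded_dbsnp: int = 0
    #: optional printed total overriding the derived tripleton+doubleton+
    #: singleton retention arithmetic (kept for published-ledger replay)
    retained_total_printed: int | None = None


@dataclass
class ValidationLedger:
    counts: ValidationCounts
    singleton_sites: int = 0
    retained_singletons: int = 0
    retained_total_derived: int = 0
    retained_total: int = 0
    analysis_sites: int = 0
    final_site_count: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "singleton_sites": self.singleton_sites,
            "retained_singletons": self.retained_singletons,
            "retained_total_derived": self.retained_total_derived,
            "retained_total": self.retained_total,
            "analysis_sites": self.analysis_sites,
            "final_site_count": self.final_site_count,
            "warnings": list(self.warnings),
        }
        d["inputs"] = {k: v for k, v in vars(self.counts).items()}
        return d


def validation_bookkeeping(counts: ValidationCounts) -> ValidationLedger:
    """Derive the retained-site arithmetic from raw validation outcomes.

    singletons        = attempted - tripletons - doubletons
    retained singles  = singletons - WGA-only
                        - (refuted + not-covered + WGA-artifact)
    retained total    = tripletons validated + doubletons validated
                        + retained singletons
    analysis sites    = initial - attempted + retained total
    final site count  = analysis sites + re-included database sites

    A printed ``retained_total_printed`` differing from the derived value is
    surfaced as a warning and then used for the downstream arithmetic (the
    published ledger is internally off by one).
    """
    c = counts
    for name, v in vars(c).items():
        if v is not None and v < 0:
            raise ValueError(f"negative input count {name}={v}")
    singles = c.attempted - c.tripleton_sites - c.doubleton_sites
    retained_singles = singles - c.singleton_wga_only - (
        c.singleton_refuted + c.singleton_not_covered + c.singleton_wga_artifact
    )
    derived = c.tripleton_validated + c.doubleton_validated + retained_singles
    msgs = []
    if singles < 0 or retained_singles < 0 or derived < 0:
        raise ValueError(
            "inconsistent validation counts: derived a negative site count "
            f"(singletons={singles}, retained singletons={retained_singles})"
        )
    retained = derived
    if c.retained_total_printed is not None:
        if c.retained_total_printed != derived:
            msg = (
                f"stated retained total {c.retained_total_printed} differs from "
                f"derived {derived} (tripletons {c.tripleton_validated} + "
                f"doubletons {c.doubleton_validated} + singletons {retained_singles})"
            )
            warnings.warn(msg, stacklevel=2)
            msgs.append(msg)
        retained = c.retained_total_printed
    analysis = c.initial_sites - c.attempted + retained
    final = analysis + c.reincluded_dbsnp
    if analysis < 0 or final < 0:
        raise ValueError("inconsistent validation counts: negative final site count")
    return ValidationLedger(
        counts=c,
        singleton_sites=singles,
        retained_singletons=retained_singles,
        retained_total_derived=derived,
        retained_total=retained,
        analysis_sites=analysis,
        final_site_count=final,
        warnings=msgs,
    )
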