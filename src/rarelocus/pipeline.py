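"""End-to-end study driver: simulate -> qc -> popgen -> assoc -> gene tests
-> model selection -> report, with on-disk artifacts at every stage."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .association import (
    PCSet,
    conditional_test,
    genotype_pca,
    ld_prune,
    ld_r2,
    residualize,
    select_array_snp,
    single_variant_test,
)
from .config import SimulationConfig
from .containers import TRAITS, GenotypeMatrix
from .genetest import build_gene_sets, gene_level_scan
from .multiplicity import FIXED_THRESHOLD, bh_threshold, bonferroni_threshold, build_report
from .popgen import (
    classify_variants,
    compute_sfs,
    pairwise_theta,
    site_mac_counts,
    watterson_theta,
)
from .qc import merge_consensus
from .selection import greedy_bic_select, variance_explained
from .simulate import Cohort, generate_cohort, sample_maf

log = logging.getLogger("rarelocus")


@dataclass
class StudyResult:
    consensus: GenotypeMatrix
    residuals: dict[str, pd.Series]
    pcs: PCSet | None
    sfs_table: pd.DataFrame
    diversity: dict
    variant_classes: pd.DataFrame
    single_results: pd.DataFrame
    gene_results: pd.DataFrame
    selection: dict[tuple[str, str], object]
    report: pd.DataFrame
    thresholds: dict
    outputs: dict[str, Path] = field(default_factory=dict)


def _trait_loci(config: SimulationConfig) -> list[tuple[str, str]]:
    """Locus-trait pairs with a configured prior association."""
    pairs = []
    for locus in config.loci:
        traits = set()
        if locus.array_snp is not None:
            traits.update(locus.array_snp.betas)
        for es in locus.rare_effect_sets:
            traits.add(es.trait)
        for t in sorted(traits):
            pairs.append((locus.gene, t))
    return pairs


def run_study(
    config: SimulationConfig | None = None,
    outdir: str | Path | None = None,
    B_permutations: int = 2_000,
    n_pcs: int = 5,
) -> StudyResult:
    """Run the full analysis pipeline on a synthetic cohort.

    Every stage consumes only the previous stage's artifacts, mirroring how
    the pipeline would run on real consensus VCFs plus phenotype tables.
    """
    if config is None:
        config = SimulationConfig()
    config.validate()
    rng_seed = config.seed
    log.info("simulating cohort: n=%d seed=%d", config.n_individuals, rng_seed)
    cohort: Cohort = generate_cohort(config)
    out: dict[str, Path] = {}
    if outdir is not None:
        out.update(io.write_fixture(cohort, Path(outdir) / "fixture"))

    # --- consensus QC ----------------------------------------------------
    cons = merge_consensus(cohort.center_callsets)
    # re-attach annotation columns lost in center site tables
    ann = cohort.genotypes.variants.set_index("variant_id")
    keep_ids = cons.consensus.variants["variant_id"]
    cons_var = ann.loc[keep_ids].reset_index()
    G = GenotypeMatrix(cons.consensus.dosages, cons.consensus.individuals, cons_var)
    log.info(
        "consensus: %d/%d sites kept, overall concordance %.4f",
        G.n_variants, len(cons.site_exclusions), cons.concordance_overall,
    )

    maf = sample_maf(G.dosages)
    seg = maf > 0
    G = G.subset_variants(seg)
    maf = maf[seg]

    # --- popgen summaries ------------------------------------------------
    sfs = compute_sfs(G)
    mac, _ = site_mac_counts(G)
    classes = classify_variants(G.variants, maf, mac)
    L = sum(l.span_bp for l in config.loci)
    diversity = {
        "S": int(G.n_variants),
        "L_bp": int(L),
        "n_chromosomes": int(sfs.n_chromosomes),
        "theta_w": watterson_theta(G.n_variants, L, sfs.n_chromosomes),
        "theta_pi": pairwise_theta(G, L),
    }
    sfs_table = pd.DataFrame(
        {"minor_allele_count": np.arange(1, len(sfs.counts) + 1), "sites": sfs.counts}
    )

    # --- residuals + PCA -------------------------------------------------
    residuals = {t: residualize(cohort.phenotypes, t).residuals for t in TRAITS}
    pcs = None
    pruned = ld_prune(G, r2_max=0.5)
    common = [j for j in pruned if maf[j] >= 0.01]
    if len(common) > n_pcs:
        pcs = genotype_pca(G, common, K=n_pcs)
    pc_scores = pcs.scores if pcs is not None else None

    # --- single-variant + conditional scans ------------------------------
    single_rows = []
    array_results = {}
    conditional_results: dict[tuple[str, str], list] = {}
    r2_with_array: dict[tuple[str, str, str], float] = {}
    variance: dict[tuple[str, str], tuple[float, float]] = {}
    selection: dict[tuple[str, str], object] = {}

    for locus_name, trait in _trait_loci(config):
        res = residuals[trait]
        in_locus = (G.variants["gene"] == locus_name).to_numpy()
        G_locus = G.subset_variants(in_locus)
        arr_mask = G_locus.variants["is_array_snp"].to_numpy()
        arr_tests = [
            single_variant_test(
                res, G_locus.dosages[:, j], G_locus.individuals, pc_scores,
                variant_id=G_locus.variants.at[j, "variant_id"], trait=trait,
            )
            for j in np.flatnonzero(arr_mask)
        ]
        if not arr_tests:
            continue
        array_id = select_array_snp(arr_tests)
        arr_result = next(r for r in arr_tests if r.variant_id == array_id)
        array_results[(locus_name, trait)] = arr_result
        arr_dos = G_locus.column(array_id)

        cond_list = []
        for j in range(G_locus.n_variants):
            vid = G_locus.variants.at[j, "variant_id"]
            marg = single_variant_test(
                res, G_locus.dosages[:, j], G_locus.individuals, pc_scores,
                variant_id=vid, trait=trait,
            )
            single_rows.append(vars(marg) | {"locus": locus_name, "kind": "marginal"})
            if vid == array_id:
                continue
            cond = conditional_test(
                res, G_locus.dosages[:, j], arr_dos, G_locus.individuals,
                pc_scores, variant_id=vid, trait=trait, array_id=array_id,
            )
            single_rows.append(vars(cond) | {"locus": locus_name, "kind": "conditional"})
            cond_list.append(cond)
            try:
                r2_with_array[(locus_name, trait, vid)] = ld_r2(
                    G_locus.dosages[:, j], arr_dos, min_overlap=2
                )
            except ValueError:
                pass
        conditional_results[(locus_name, trait)] = cond_list

        # model selection + variance accounting per locus-trait
        sel = greedy_bic_select(res, G_locus, pc_scores, locus=locus_name, trait=trait)
        selection[(locus_name, trait)] = sel
        indep = [
            r.variant_id for r in cond_list
            if np.isfinite(r.p) and r.p < FIXED_THRESHOLD
            and r2_with_array.get((locus_name, trait, r.variant_id), 1.0) < 0.20
        ]
        variance[(locus_name, trait)] = variance_explained(
            res, G_locus, indep, array_id, pc_scores
        )

    single_df = pd.DataFrame(single_rows)

    # --- gene-level tests -------------------------------------------------
    gene_rows = []
    gene_sets = build_gene_sets(G)
    pc_df = (
        pd.DataFrame(pc_scores, index=G.individuals) if pc_scores is not None else None
    )
    for locus_name, trait in _trait_loci(config):
        sets = [gs for gs in gene_sets if gs.gene == locus_name]
        for r in gene_level_scan(
            sets, residuals[trait], trait, pc_df, B=B_permutations, seed=rng_seed
        ):
            gene_rows.append(vars(r))
    gene_df = pd.DataFrame(gene_rows)

    # --- multiplicity + report -------------------------------------------
    pooled_p = []
    pooled_ids = []
    if len(single_df):
        ok = single_df["kind"].eq("marginal") & np.isfinite(single_df["p"])
        pooled_p += list(single_df.loc[ok, "p"])
        pooled_ids += [
            f"single:{l}:{t}:{v}" for l, t, v in zip(
                single_df.loc[ok, "locus"], single_df.loc[ok, "trait"],
                single_df.loc[ok, "variant_id"])
        ]
    if len(gene_df):
        pooled_p += list(gene_df["cmc_p"]) + list(gene_df["skat_p"])
        pooled_ids += [f"cmc:{g}:{t}" for g, t in zip(gene_df["gene"], gene_df["trait"])]
        pooled_ids += [f"skat:{g}:{t}" for g, t in zip(gene_df["gene"], gene_df["trait"])]
    thresholds = {"fixed_threshold": FIXED_THRESHOLD, "m_tests": len(pooled_p)}
    if pooled_p:
        bh = bh_threshold(np.clip(pooled_p, 1e-300, 1.0), q=0.05, test_ids=pooled_ids)
        thresholds |= {
            "bh_cutoff_q05": bh.cutoff,
            "bh_significant": bh.significant,
            "bonferroni_cutoff_a05": bonferroni_threshold(0.05, len(pooled_p)),
        }
    report = build_report(
        array_results, conditional_results, G.variants, r2_with_array, variance
    ) if array_results else pd.DataFrame()

    result = StudyResult(
        consensus=G, residuals=residuals, pcs=pcs, sfs_table=sfs_table,
        diversity=diversity, variant_classes=classes, single_results=single_df,
        gene_results=gene_df, selection=selection, report=report,
        thresholds=thresholds, outputs=out,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: StudyResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.sfs_table.to_csv(outdir / "sfs.tsv", sep="\t", index=False)
    with open(outdir / "diversity.json", "w") as fh:
        json.dump(result.diversity, fh, indent=1)
    result.variant_classes.to_csv(outdir / "variant_classes.tsv", sep="\t", index=False)
    if len(result.single_results):
        result.single_results.to_csv(outdir / "association.tsv", sep="\t", index=False)
    if len(result.gene_results):
        result.gene_results.to_csv(outdir / "gene_tests.tsv", sep="\t", index=False)
    if len(result.report):
        result.report.to_csv(outdir / "report_locus_trait.tsv", sep="\t", index=False)
    sel_rows = []
    for (locus, trait), sel in result.selection.items():
        sel_rows.append({
            "locus": locus, "trait": trait,
            "selected": ";".join(sel.selected),
            "bic_trace": ";".join(f"{b:.3f}" for b in sel.bic_trace),
            "n": sel.n,
        })
    if sel_rows:
        pd.DataFrame(sel_rows).to_csv(outdir / "model_selection.tsv", sep="\t", index=False)
    with open(outdir / "thresholds.json", "w") as fh:
        json.dump(result.thresholds, fh, indent=1)
    result.outputs.update({p.name: p for p in outdir.glob("*.tsv")})
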