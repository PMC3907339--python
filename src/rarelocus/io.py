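"""Fixture I/O: VCF v4.2, phenotype/annotation TSVs, BED targets, truth JSON.

Writing emits minimal, grammatically valid VCF text (GT-only FORMAT);
reading goes through cyvcf2 so anything the pipeline consumes has passed a
real VCF parser.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import MISSING, CenterCallSet, GenotypeMatrix, TrueModel
from .simulate import Cohort

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write dosages as an uncompressed VCF v4.2 with GT genotypes."""
    path = Path(path)
    var = G.variants
    try:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for chrom in pd.unique(var["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(G.individuals)
                + "\n"
            )
            for j in range(G.n_variants):
                row = var.iloc[j]
                gts = "\t".join(_GT[int(d)] for d in G.dosages[:, j])
                fh.write(
                    f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t"
                    f"{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
                )
    except OSError as exc:  # pragma: no cover
        raise OSError(f"failed writing VCF to {path}: {exc}") from exc


def read_vcf(path) -> GenotypeMatrix:
    """Read a (possibly multi-allelic) VCF into a GenotypeMatrix.

    Multi-allelic records keep their comma-joined ALT string; their
    genotypes are read as alternate-allele dosage like biallelic sites
    (downstream consensus merging excludes such sites anyway).
    """
    path = str(path)
    vcf = VCF(path)
    individuals = list(vcf.samples)
    dosages, rows = [], []
    for rec in vcf:
        gt = np.asarray(rec.gt_types)
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        dos = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        dosages.append(dos.astype(np.int8))
        rows.append(
            {
                "variant_id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": ",".join(rec.ALT),
            }
        )
    vcf.close()
    if not rows:
        return GenotypeMatrix(
            np.empty((len(individuals), 0), dtype=np.int8),
            individuals,
            pd.DataFrame(columns=["variant_id", "chrom", "pos", "ref", "alt"]),
        )
    return GenotypeMatrix(np.column_stack(dosages), individuals, pd.DataFrame(rows))


def read_center_callset(path, center: str) -> CenterCallSet:
    G = read_vcf(path)
    return CenterCallSet(center, G.dosages, G.individuals, G.variants)


PHENOTYPE_COLUMNS = [
    "id", "cohort", "case_status", "age", "sex", "oc_use", "pregnant",
    "TG", "HDLC", "LDLC", "TC", "FG", "FI",
]


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes[PHENOTYPE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table {path} lacks columns: {sorted(missing)}")
    return df


def write_annotations(variants: pd.DataFrame, path) -> None:
    variants[["variant_id", "gene", "consequence"]].to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"variant_id", "gene", "consequence"} - set(df.columns)
    if missing:
        raise ValueError(f"annotation table {path} lacks columns: {sorted(missing)}")
    return df


def write_targets_bed(config_or_variants, path) -> None:
    """BED of targeted regions (0-based half-open), one row per locus."""
    rows = []
    loci = getattr(config_or_variants, "loci", None)
    if loci is not None:
        for locus in loci:
            rows.append((locus.chrom, locus.start, locus.start + locus.span_bp, locus.gene))
    else:
        for gene, grp in config_or_variants.groupby("gene", sort=False):
            rows.append((grp["chrom"].iloc[0], int(grp["pos"].min()) - 1,
                         int(grp["pos"].max()), gene))
    with open(path, "w") as fh:
        for chrom, start, end, name in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_targets_bed(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "name"],
        dtype={"chrom": str},
    )


def write_fixture(cohort: Cohort, outdir) -> dict[str, Path]:
    """Write a complete on-disk study fixture; returns the path map.

    Emits ``truth.vcf``, per-center VCFs, ``phenotypes.tsv``,
    ``annotations.tsv``, ``targets.bed`` and ``true_model.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["truth_vcf"] = outdir / "truth.vcf"
    write_vcf(cohort.genotypes, paths["truth_vcf"])
    for cs in cohort.center_callsets:
        key = f"{cs.center}_vcf"
        paths[key] = outdir / f"{cs.center}.vcf"
        write_vcf(cs.as_matrix(), paths[key])
    paths["phenotypes"] = outdir / "phenotypes.tsv"
    write_phenotypes(cohort.phenotypes, paths["phenotypes"])
    paths["annotations"] = outdir / "annotations.tsv"
    write_annotations(cohort.genotypes.variants, paths["annotations"])
    paths["targets"] = outdir / "targets.bed"
    write_targets_bed(cohort.config, paths["targets"])
    paths["true_model"] = outdir / "true_model.json"
    with open(paths["true_model"], "w") as fh:
        json.dump(cohort.true_model.to_dict(), fh, indent=1)
    return paths


def read_true_model(path) -> TrueModel:
    with open(path) as fh:
        return TrueModel.from_dict(json.load(fh))
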