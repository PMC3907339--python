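"""Core in-memory containers shared across the pipeline.

Genotypes live in a dense ``int8`` individuals x variants dosage matrix with
``-1`` marking missing calls; variant metadata rides alongside in a pandas
DataFrame so downstream stages never have to re-parse a VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: canonical variant annotation vocabulary (functional consequence classes)
CONSEQUENCES = (
    "nonsense",
    "missense_probably",
    "missense_possibly",
    "missense_benign",
    "synonymous",
    "utr5",
    "utr3",
    "intron",
)

#: coding, protein-altering classes used by gene-level rare-variant tests
NONSYNONYMOUS = (
    "nonsense",
    "missense_probably",
    "missense_possibly",
    "missense_benign",
)

#: classes counted as predicted deleterious (nonsense + probably-damaging)
DELETERIOUS = ("nonsense", "missense_probably")

#: the six quantitative metabolic traits analysed by the pipeline
TRAITS = ("TG", "HDLC", "LDLC", "TC", "FG", "FI")

#: traits modelled (and association-tested) on the natural-log scale
LOG_TRAITS = ("TG", "FG", "FI")


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with variant metadata.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_variants)`` int8 array of alternate-allele
        dosages 0/1/2, with :data:`MISSING` (-1) for no-calls.
    individuals
        Sample identifiers, one per row.
    variants
        One row per column of ``dosages``. Required columns:
        ``variant_id, chrom, pos, ref, alt``; the simulator and annotation
        reader add ``gene, consequence, is_array_snp``.
    """

    dosages: np.ndarray
    individuals: list[str]
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x variants)")
        n, m = self.dosages.shape
        if len(self.individuals) != n:
            raise ValueError(
                f"{len(self.individuals)} individual ids for {n} dosage rows"
            )
        if len(self.variants) != m:
            raise ValueError(
                f"{len(self.variants)} variant rows for {m} dosage columns"
            )
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["variant_id"])

    def column(self, variant_id: str) -> np.ndarray:
        """Dosage vector for one variant id."""
        idx = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not in matrix")
        return self.dosages[:, idx[0]]

    def subset_variants(self, mask_or_ids) -> "GenotypeMatrix":
        if isinstance(mask_or_ids, (list, tuple, pd.Index)):
            keep = self.variants["variant_id"].isin(list(mask_or_ids)).to_numpy()
        else:
            keep = np.asarray(mask_or_ids, dtype=bool)
        return GenotypeMatrix(
            self.dosages[:, keep],
            list(self.individuals),
            self.variants.loc[keep].reset_index(drop=True),
        )

    def subset_individuals(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            self.dosages[mask],
            [s for s, k in zip(self.individuals, mask) if k],
            self.variants.copy(),
        )


@dataclass
class CenterCallSet:
    """One sequencing center's genotype calls over the pooled site list."""

    center: str
    dosages: np.ndarray
    individuals: list[str]
    variants: pd.DataFrame  # variant_id, chrom, pos, ref, alt

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)

    def as_matrix(self) -> GenotypeMatrix:
        return GenotypeMatrix(self.dosages, list(self.individuals), self.variants)


@dataclass
class TrueModel:
    """Ground truth planted by the synthetic cohort generator.

    ``betas`` maps trait -> {variant_id: per-allele effect}, on the analysis
    scale of the trait (log scale for log-modelled traits), in units of the
    trait's residual SD. ``variance_explained`` holds the additive-variance
    fraction 2p(1-p)beta^2 each planted signal contributes.
    """

    betas: dict[str, dict[str, float]] = field(default_factory=dict)
    variance_explained: dict[str, dict[str, float]] = field(default_factory=dict)
    artifact_multiallelic: list[str] = field(default_factory=list)
    artifact_alt_mismatch: list[str] = field(default_factory=list)
    monomorphic_sites: list[str] = field(default_factory=list)

    def causal_ids(self, trait: str | None = None) -> list[str]:
        if trait is not None:
            return sorted(self.betas.get(trait, {}))
        out: set[str] = set()
        for d in self.betas.values():
            out.update(d)
        return sorted(out)

    def to_dict(self) -> dict:
        return {
            "betas": self.betas,
            "variance_explained": self.variance_explained,
            "artifact_multiallelic": self.artifact_multiallelic,
            "artifact_alt_mismatch": self.artifact_alt_mismatch,
            "monomorphic_sites": self.monomorphic_sites,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrueModel":
        return cls(
            betas={t: dict(v) for t, v in d.get("betas", {}).items()},
            variance_explained={
                t: dict(v) for t, v in d.get("variance_explained", {}).items()
            },
            artifact_multiallelic=list(d.get("artifact_multiallelic", [])),
            artifact_alt_mismatch=list(d.get("artifact_alt_mismatch", [])),
            monomorphic_sites=list(d.get("monomorphic_sites", [])),
        )
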