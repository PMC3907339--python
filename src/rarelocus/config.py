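"""Simulation configuration: locus architectures, cohort design, noise rates.

The default configuration emulates a bottlenecked-founder-population targeted
re-sequencing study: a large birth-cohort arm plus a smaller case-control arm
(6,123 individuals at full scale, split 4,447 / 836 controls / 840 cases),
an allele-frequency spectrum skewed away from singletons toward 0.5-2%
("Goldilocks") alleles, six covariate-influenced metabolic traits, and loci
carrying one common array-SNP signal plus independent rare signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .containers import CONSEQUENCES, TRAITS

COHORTS = ("cohortA", "cohortB-control", "cohortB-case")

DEFAULT_CONSEQUENCE_MIX = {
    # roughly 60% coding (37% NS / 23% synonymous) and 40% UTR+intron
    "nonsense": 0.015,
    "missense_probably": 0.13,
    "missense_possibly": 0.07,
    "missense_benign": 0.155,
    "synonymous": 0.23,
    "utr5": 0.08,
    "utr3": 0.12,
    "intron": 0.20,
}


@dataclass
class RareEffectSet:
    """A planted set of causal rare variants for one trait at one locus."""

    trait: str
    n_causal: int
    maf_ceiling: float = 0.01
    effect_sd: float = 0.4  # per-allele effect in residual-SD units
    direction_mode: str = "same"  # "same" | "mixed"

    def validate(self) -> None:
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}")
        if self.direction_mode not in ("same", "mixed"):
            raise ValueError(f"direction_mode must be same|mixed, got {self.direction_mode!r}")
        if not 0 < self.maf_ceiling <= 0.5:
            raise ValueError("maf_ceiling must be in (0, 0.5]")
        if self.n_causal < 1:
            raise ValueError("n_causal must be >= 1")


@dataclass
class ArraySnpSpec:
    """The locus's common GWAS-array SNP and its per-trait effects."""

    maf: float
    betas: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValueError("array SNP MAF must be in (0, 0.5]")
        for t in self.betas:
            if t not in TRAITS:
                raise ValueError(f"unknown trait {t!r} in array SNP betas")


@dataclass
class LocusSpec:
    """One targeted locus: a gene, its coding span and variant architecture."""

    gene: str
    chrom: str = "1"
    start: int = 1_000_000
    span_bp: int = 10_000
    n_variants: int = 60
    consequence_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONSEQUENCE_MIX)
    )
    array_snp: ArraySnpSpec | None = None
    rare_effect_sets: list[RareEffectSet] = field(default_factory=list)

    def validate(self) -> None:
        total = sum(self.consequence_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"consequence mix for {self.gene} sums to {total}, not 1")
        unknown = set(self.consequence_mix) - set(CONSEQUENCES)
        if unknown:
            raise ValueError(f"unknown consequence classes: {sorted(unknown)}")
        if self.array_snp is not None:
            self.array_snp.validate()
        for s in self.rare_effect_sets:
            s.validate()
        if self.span_bp < self.n_variants:
            raise ValueError("span_bp must be at least n_variants")


@dataclass
class BottleneckSpec:
    """Two-epoch demographic model shaping the allele-frequency spectrum.

    ``mode="parametric"`` (default) reweights the neutral 1/p frequency
    density toward intermediate frequencies with mixture weight
    ``goldilocks_weight``; ``mode="wright_fisher"`` runs a forward two-epoch
    binomial drift simulation with the stated sizes.
    """

    enabled: bool = True
    mode: str = "parametric"  # "parametric" | "wright_fisher"
    goldilocks_weight: float = 0.25
    ancestral_size: int = 10_000
    bottleneck_size: int = 300
    generations_post: int = 100

    def validate(self) -> None:
        if self.mode not in ("parametric", "wright_fisher"):
            raise ValueError(f"unknown bottleneck mode {self.mode!r}")
        if self.enabled and self.mode == "wright_fisher" and self.bottleneck_size < 2:
            raise ValueError("bottleneck_size must be >= 2")
        if not 0 <= self.goldilocks_weight <= 1:
            raise ValueError("goldilocks_weight must be in [0, 1]")


# Plausible metabolic-trait location/scale defaults (mmol/L; FI in mU/L).
# Log-scale traits (TG, FG, FI) state the mean/SD of the log of the trait.
DEFAULT_TRAIT_MEANS = {
    "TG": 0.1,   # log mmol/L  (median TG ~ 1.1 mmol/L)
    "HDLC": 1.5,
    "LDLC": 3.3,
    "TC": 5.2,
    "FG": 1.6,   # log mmol/L  (median FG ~ 5.0 mmol/L)
    "FI": 2.1,   # log mU/L    (median FI ~ 8 mU/L)
}

DEFAULT_RESIDUAL_SD = {
    "TG": 0.45,
    "HDLC": 0.33,
    "LDLC": 0.85,
    "TC": 1.0,
    "FG": 0.08,
    "FI": 0.5,
}

# Per-trait covariate coefficients: age (per year, centered at 45), age^2,
# sex (female=1), oral-contraceptive use, pregnancy, cohort (cohortB=1).
DEFAULT_COVARIATE_EFFECTS = {
    "TG": {"age": 0.004, "age2": -1e-4, "sex": -0.08, "oc": 0.10, "pregnancy": 0.15, "cohort": 0.02},
    "HDLC": {"age": 0.002, "age2": 0.0, "sex": 0.25, "oc": 0.08, "pregnancy": 0.05, "cohort": -0.02},
    "LDLC": {"age": 0.02, "age2": -2e-4, "sex": -0.15, "oc": 0.05, "pregnancy": 0.10, "cohort": 0.03},
    "TC": {"age": 0.025, "age2": -2e-4, "sex": -0.10, "oc": 0.06, "pregnancy": 0.12, "cohort": 0.03},
    "FG": {"age": 0.0015, "age2": 1e-5, "sex": -0.015, "oc": 0.002, "pregnancy": -0.01, "cohort": 0.005},
    "FI": {"age": 0.004, "age2": 5e-5, "sex": -0.03, "oc": 0.01, "pregnancy": 0.08, "cohort": 0.02},
}


def default_loci() -> list[LocusSpec]:
    """Three-locus reference architecture.

    One HDL-C locus with a common array SNP plus same-direction rare NS
    effects, one with a strong array SNP plus mixed-direction rare effects,
    and one fasting-glucose locus carrying a single Goldilocks-frequency
    damaging missense signal independent of the array SNP.
    """
    return [
        LocusSpec(
            gene="ABCA1",
            chrom="9",
            start=107_543_000,
            span_bp=11_176,
            n_variants=73,
            array_snp=ArraySnpSpec(maf=0.30, betas={"HDLC": -0.08, "TC": -0.05}),
            rare_effect_sets=[
                RareEffectSet("HDLC", n_causal=8, effect_sd=0.4, direction_mode="same"),
                RareEffectSet("TC", n_causal=8, effect_sd=0.35, direction_mode="same"),
            ],
        ),
        LocusSpec(
            gene="CETP",
            chrom="16",
            start=56_733_000,
            span_bp=16_686,
            n_variants=65,
            array_snp=ArraySnpSpec(maf=0.27, betas={"HDLC": 0.27}),
            rare_effect_sets=[
                RareEffectSet("HDLC", n_causal=8, effect_sd=0.4, direction_mode="mixed"),
            ],
        ),
        LocusSpec(
            gene="G6PC2",
            chrom="2",
            start=169_312_000,
            span_bp=17_240,
            n_variants=60,
            array_snp=ArraySnpSpec(maf=0.31, betas={"FG": -0.15}),
            rare_effect_sets=[
                RareEffectSet("FG", n_causal=1, maf_ceiling=0.02, effect_sd=0.41, direction_mode="same"),
            ],
        ),
    ]


@dataclass
class SimulationConfig:
    """Full synthetic-study design.

    Defaults reproduce the reference study conditions: 6,123 individuals
    split 4,447 (population cohort) / 836 (case-control controls) / 840
    (cases), a parametric bottleneck SFS, per-genotype center error rate of
    2e-4 (matching ~99.96% pairwise concordance) and 0.2% missingness.
    """

    n_individuals: int = 6123
    cohort_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "cohortA": 4447 / 6123,
            "cohortB-control": 836 / 6123,
            "cohortB-case": 840 / 6123,
        }
    )
    loci: list[LocusSpec] = field(default_factory=default_loci)
    bottleneck: BottleneckSpec = field(default_factory=BottleneckSpec)
    trait_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TRAIT_MEANS))
    residual_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RESIDUAL_SD))
    covariate_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {t: dict(v) for t, v in DEFAULT_COVARIATE_EFFECTS.items()}
    )
    substructure_fst: float = 0.0
    center_error_rate: float = 2e-4
    center_missing_rate: float = 2e-3
    n_artifact_multiallelic: int = 0
    n_artifact_alt_mismatch: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 50:
            raise ValueError("n_individuals must be >= 50")
        if set(self.cohort_fractions) != set(COHORTS):
            raise ValueError(f"cohort_fractions must cover exactly {COHORTS}")
        total = sum(self.cohort_fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"cohort fractions sum to {total}, not 1")
        for rate in (self.center_error_rate, self.center_missing_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must be in [0, 1]")
        if not 0 <= self.substructure_fst <= 0.1:
            raise ValueError("substructure_fst must be in [0, 0.1]")
        for t in TRAITS:
            if self.residual_sd[t] < 0:
                raise ValueError(f"residual_sd for {t} must be non-negative")
        self.bottleneck.validate()
        for locus in self.loci:
            locus.validate()

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "bottleneck" in d and isinstance(d["bottleneck"], dict):
            d["bottleneck"] = BottleneckSpec(**d["bottleneck"])
        loci = []
        for ld in d.get("loci", []):
            if isinstance(ld, LocusSpec):
                loci.append(ld)
                continue
            ld = dict(ld)
            if ld.get("array_snp") is not None:
                ld["array_snp"] = ArraySnpSpec(**ld["array_snp"])
            ld["rare_effect_sets"] = [
                RareEffectSet(**s) if not isinstance(s, RareEffectSet) else s
                for s in ld.get("rare_effect_sets", [])
            ]
            loci.append(LocusSpec(**ld))
        if loci:
            d["loci"] = loci
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            cfg = cls.from_dict(yaml.safe_load(fh) or {})
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
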