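"""Synthetic founder-population cohort generator.

Produces every input the downstream pipeline consumes — genotypes, variant
annotations, covariate-influenced phenotypes, three noisy per-center call
sets and the planted ground truth — so the full analysis is exercisable
without any external data.

The allele-frequency model emulates a population that expanded from a severe
bottleneck: relative to the neutral outbred expectation (site-frequency
spectrum proportional to 1/i), the spectrum has a depressed singleton
fraction and an excess of 0.5-2% "Goldilocks" alleles. The default is a
cheap parametric mixture over the frequency density; a forward two-epoch
Wright-Fisher mode is available when an explicit demographic history is
wanted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import COHORTS, LocusSpec, SimulationConfig
from .containers import (
    MISSING,
    TRAITS,
    CenterCallSet,
    GenotypeMatrix,
    TrueModel,
)

# Named substreams: each stage draws from its own child of the master seed so
# that stages are independently reproducible.
_STAGES = (
    "frequencies",
    "genotypes",
    "covariates",
    "phenotypes",
    "effects",
    "centers",
)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random generator fanned out from one seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {_STAGES}")
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGES.index(stage),))
    )


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def _neutral_frequencies(n_sites: int, rng: np.random.Generator, p_min: float) -> np.ndarray:
    """Draw population frequencies from the neutral density f(p) ~ 1/p.

    Inverse-CDF sampling on [p_min, 0.5]: p = p_min * (0.5/p_min)**u.
    """
    u = rng.uniform(size=n_sites)
    return p_min * (0.5 / p_min) ** u


def _wright_fisher_frequencies(
    n_sites: int, rng: np.random.Generator, ancestral: int, bottleneck: int,
    generations_post: int, p_min: float,
) -> np.ndarray:
    """Forward two-epoch drift: one bottleneck generation, then recovery."""
    p = _neutral_frequencies(n_sites, rng, p_min)
    # severe subsampling through the bottleneck
    p = rng.binomial(2 * bottleneck, p) / (2.0 * bottleneck)
    for _ in range(generations_post):
        alive = (p > 0) & (p < 1)
        if not alive.any():
            break
        p[alive] = rng.binomial(2 * ancestral, p[alive]) / (2.0 * ancestral)
    return p


def simulate_allele_frequencies(
    config: SimulationConfig, rng: np.random.Generator | None = None,
    n_sites: int | None = None,
) -> np.ndarray:
    """Population minor-allele frequencies for every variant in the design.

    Frequencies are folded to (0, 0.5] and conditioned on being likely to
    segregate in a sample of ``2 * n_individuals`` chromosomes (sites almost
    certain to be monomorphic in-sample are redrawn).

    Parameters
    ----------
    config
        Validated simulation design; ``config.bottleneck`` selects the
        frequency model.
    rng
        Optional generator; defaults to the ``frequencies`` substream of
        ``config.seed``.
    n_sites
        Override the total variant count (defaults to the sum of per-locus
        ``n_variants``).
    """
    config.validate()
    if rng is None:
        rng = stage_rng(config.seed, "frequencies")
    if n_sites is None:
        n_sites = sum(locus.n_variants for locus in config.loci)
    two_n = 2 * config.n_individuals
    p_min = 1.0 / (4.0 * config.n_individuals)
    bn = config.bottleneck

    out = np.empty(0)
    # rejection loop: condition on segregating in the sample
    while out.size < n_sites:
        need = max(n_sites - out.size, 64)
        if not bn.enabled:
            p = _neutral_frequencies(need, rng, p_min)
        elif bn.mode == "parametric":
            goldi = rng.uniform(size=need) < bn.goldilocks_weight
            p = _neutral_frequencies(need, rng, p_min)
            # intermediate-frequency component: Beta(2, 150), mode ~0.7%,
            # bulk of its mass inside the 0.5-2% Goldilocks band
            p[goldi] = rng.beta(2.0, 150.0, size=goldi.sum())
        else:
            p = _wright_fisher_frequencies(
                need, rng, bn.ancestral_size, bn.bottleneck_size,
                bn.generations_post, p_min,
            )
        p = np.minimum(p, 1.0 - p)  # fold to minor allele
        p = p[p > 0]
        p_seg = -np.expm1(two_n * np.log1p(-np.minimum(p, 0.999999)))
        keep = rng.uniform(size=p.size) < p_seg
        out = np.concatenate([out, p[keep]])
    return out[:n_sites]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _variant_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lay variants out along each locus with consequence annotations."""
    rows = []
    for locus in config.loci:
        pos = np.sort(
            rng.choice(np.arange(locus.span_bp), size=locus.n_variants, replace=False)
        ) + locus.start
        classes = list(locus.consequence_mix)
        probs = np.array([locus.consequence_mix[c] for c in classes], dtype=float)
        probs /= probs.sum()
        cons = rng.choice(classes, size=locus.n_variants, p=probs)
        ref_idx = rng.integers(0, 4, size=locus.n_variants)
        alt_idx = (ref_idx + rng.integers(1, 4, size=locus.n_variants)) % 4
        for k in range(locus.n_variants):
            rows.append(
                {
                    "variant_id": f"{locus.gene}:{locus.chrom}:{pos[k]}",
                    "chrom": locus.chrom,
                    "pos": int(pos[k]),
                    "ref": _BASES[ref_idx[k]],
                    "alt": _BASES[alt_idx[k]],
                    "gene": locus.gene,
                    "consequence": cons[k],
                    "is_array_snp": False,
                }
            )
    return pd.DataFrame(rows)


def simulate_genotypes(
    freqs: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    variants: pd.DataFrame | None = None,
    cohorts: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Hardy-Weinberg binomial genotypes at the given population MAFs.

    With ``substructure_fst > 0`` the two cohort arms are treated as two
    subpopulations whose frequencies are drawn from a Balding-Nichols Beta
    distribution around each site's ancestral frequency.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs <= 0) | (freqs > 0.5)):
        raise ValueError("frequencies must be folded minor-allele values in (0, 0.5]")
    if rng is None:
        rng = stage_rng(config.seed, "genotypes")
    n = config.n_individuals
    m = freqs.size
    if variants is None:
        variants = _variant_table(config, rng)
        if len(variants) != m:
            # ad-hoc frequency vector: fall back to a generic site table
            variants = pd.DataFrame(
                {
                    "variant_id": [f"site:1:{1000 + 10 * j}" for j in range(m)],
                    "chrom": "1",
                    "pos": [1000 + 10 * j for j in range(m)],
                    "ref": "A",
                    "alt": "C",
                    "gene": "GENE1",
                    "consequence": "missense_benign",
                    "is_array_snp": False,
                }
            )
    if cohorts is None:
        cohorts = assign_cohorts(config)

    fst = config.substructure_fst
    if fst > 0:
        a = freqs * (1 - fst) / fst
        b = (1 - freqs) * (1 - fst) / fst
        in_b = np.char.startswith(cohorts.astype(str), "cohortB")
        p_sub = {
            False: rng.beta(a, b),
            True: rng.beta(a, b),
        }
        dos = np.empty((n, m), dtype=np.int8)
        for flag in (False, True):
            rows = in_b == flag
            dos[rows] = rng.binomial(2, p_sub[flag], size=(rows.sum(), m))
    else:
        dos = rng.binomial(2, freqs, size=(n, m)).astype(np.int8)

    individuals = [f"I{i:06d}" for i in range(n)]
    return GenotypeMatrix(dos, individuals, variants)


def correlated_dosages(
    freq: float, r: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two dosage vectors whose haplotypes share correlation ``r``.

    Used to plant an LD partner for an array SNP (the only LD structure the
    generator models). Each of the two haplotypes per individual copies the
    first SNP's allele with probability ``r`` and draws fresh otherwise, so
    the haplotype (and hence dosage) correlation is ``r`` in expectation and
    the dosage r-squared is ``r**2``.
    """
    hap_a = rng.uniform(size=(n, 2)) < freq
    copy = rng.uniform(size=(n, 2)) < r
    fresh = rng.uniform(size=(n, 2)) < freq
    hap_b = np.where(copy, hap_a, fresh)
    return hap_a.sum(1).astype(np.int8), hap_b.sum(1).astype(np.int8)


def assign_cohorts(config: SimulationConfig) -> np.ndarray:
    """Deterministic cohort labels honouring the configured fractions."""
    n = config.n_individuals
    counts = {c: int(round(config.cohort_fractions[c] * n)) for c in COHORTS}
    # fix rounding drift on the largest arm
    drift = n - sum(counts.values())
    counts["cohortA"] += drift
    labels = np.concatenate([np.repeat(c, counts[c]) for c in COHORTS])
    return labels


# ---------------------------------------------------------------------------
# causal architecture + phenotypes
# ---------------------------------------------------------------------------

def plant_effects(
    G: GenotypeMatrix, config: SimulationConfig, rng: np.random.Generator | None = None
) -> TrueModel:
    """Choose causal variants per locus and assign per-trait betas.

    Array SNPs get their configured common-variant effects; each rare effect
    set samples ``n_causal`` non-synonymous variants under its MAF ceiling,
    with all-positive betas under ``direction_mode="same"`` and alternating
    signs under ``"mixed"``. Betas are stored on the residual-SD scale of
    the trait and converted to trait units at phenotype generation.
    """
    if rng is None:
        rng = stage_rng(config.seed, "effects")
    model = TrueModel()
    maf = sample_maf(G.dosages)
    var = G.variants
    ns_mask = var["consequence"].isin(
        ("nonsense", "missense_probably", "missense_possibly", "missense_benign")
    ).to_numpy()
    for locus in config.loci:
        in_locus = (var["gene"] == locus.gene).to_numpy()
        if locus.array_snp is not None:
            arr_id = var.loc[in_locus & var["is_array_snp"].to_numpy(), "variant_id"]
            if len(arr_id) != 1:
                raise ValueError(f"locus {locus.gene} lacks a designated array SNP")
            arr_id = arr_id.iloc[0]
            for trait, beta in locus.array_snp.betas.items():
                model.betas.setdefault(trait, {})[arr_id] = float(beta)
        for es in locus.rare_effect_sets:
            pool = np.flatnonzero(
                in_locus & ns_mask & (maf > 0) & ~var["is_array_snp"].to_numpy()
            )
            if pool.size < es.n_causal:
                raise ValueError(
                    f"locus {locus.gene}: only {pool.size} polymorphic NS "
                    f"variants for an effect set of {es.n_causal}"
                )
            eligible = pool[maf[pool] < es.maf_ceiling]
            if eligible.size >= es.n_causal:
                chosen = rng.choice(eligible, size=es.n_causal, replace=False)
            else:
                # small samples may realize too few strictly-rare NS sites;
                # fall back to the rarest available and say so
                warnings.warn(
                    f"locus {locus.gene}: only {eligible.size} NS variants under "
                    f"MAF {es.maf_ceiling}; padding with the rarest available",
                    stacklevel=2,
                )
                extra = pool[maf[pool] >= es.maf_ceiling]
                extra = extra[np.argsort(maf[extra], kind="stable")]
                chosen = np.concatenate(
                    [eligible, extra[: es.n_causal - eligible.size]]
                )
            signs = np.ones(es.n_causal)
            if es.direction_mode == "mixed":
                signs[1::2] = -1.0
            for j, s in zip(chosen, signs):
                vid = var.at[j, "variant_id"]
                model.betas.setdefault(es.trait, {})[vid] = float(s * es.effect_sd)
    # additive variance ledger: per-signal 2p(1-p)beta^2 (residual-variance
    # units), normalized by the trait's total variance so fractions sum < 1
    for trait, d in model.betas.items():
        h2 = {}
        for vid, beta_sd in d.items():
            p = sample_maf(G.column(vid)[None, :].T)[0]
            h2[vid] = 2 * p * (1 - p) * beta_sd**2
        total = 1.0 + sum(h2.values())
        model.variance_explained[trait] = {v: float(x / total) for v, x in h2.items()}
    return model


def sample_maf(dosages: np.ndarray) -> np.ndarray:
    """Folded in-sample MAF per column, ignoring missing calls."""
    d = np.asarray(dosages)
    valid = d != MISSING
    alt = np.where(valid, d, 0).sum(0)
    two_n = 2 * valid.sum(0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(two_n > 0, alt / np.maximum(two_n, 1), np.nan)
    return np.minimum(p, 1 - p)


def simulate_covariates(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-individual demographic covariates and cohort/case labels."""
    if rng is None:
        rng = stage_rng(config.seed, "covariates")
    n = config.n_individuals
    cohorts = assign_cohorts(config)
    age = rng.uniform(31.0, 62.0, size=n)
    sex = rng.integers(0, 2, size=n)  # 1 = female
    oc = np.where((sex == 1) & (age < 50), rng.uniform(size=n) < 0.2, False)
    pregnant = np.where(
        (sex == 1) & (age < 45) & ~oc, rng.uniform(size=n) < 0.03, False
    )
    return pd.DataFrame(
        {
            "id": [f"I{i:06d}" for i in range(n)],
            "cohort": cohorts,
            "case_status": (cohorts == "cohortB-case").astype(int),
            "age": age,
            "sex": sex,
            "oc_use": oc.astype(int),
            "pregnant": pregnant.astype(int),
        }
    )


def simulate_phenotypes(
    G: GenotypeMatrix,
    model: TrueModel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Traits = covariate linear predictor + genetic effects + Gaussian noise.

    Log-scale traits (TG, FG, FI) are generated so the *log* of the trait is
    linear in the predictors; the returned table holds natural-scale values.
    """
    for t in TRAITS:
        if config.residual_sd[t] < 0:
            raise ValueError("residual_sd must be non-negative")
    missing_causal = [v for v in model.causal_ids() if v not in set(G.variant_ids)]
    if missing_causal:
        raise ValueError(f"causal variants absent from genotype matrix: {missing_causal}")
    if rng is None:
        rng = stage_rng(config.seed, "phenotypes")
    if covariates is None:
        covariates = simulate_covariates(config)
    cov = covariates
    n = len(cov)
    age_c = cov["age"].to_numpy() - 45.0
    in_b = cov["cohort"].str.startswith("cohortB").to_numpy().astype(float)

    out = cov.copy()
    for trait in TRAITS:
        eff = config.covariate_effects[trait]
        sd = config.residual_sd[trait]
        y = (
            config.trait_means[trait]
            + eff["age"] * age_c
            + eff["age2"] * age_c**2
            + eff["sex"] * cov["sex"].to_numpy()
            + eff["oc"] * cov["oc_use"].to_numpy()
            + eff["pregnancy"] * cov["pregnant"].to_numpy()
            + eff["cohort"] * in_b
        )
        for vid, beta_sd in model.betas.get(trait, {}).items():
            d = G.column(vid).astype(float)
            d[d == MISSING] = 0.0
            y = y + beta_sd * sd * d
        y = y + rng.normal(0.0, sd, size=n)
        if trait in ("TG", "FG", "FI"):
            y = np.exp(y)
        out[trait] = y
    return out


# ---------------------------------------------------------------------------
# per-center replicate call sets
# ---------------------------------------------------------------------------

def simulate_center_callsets(
    G: GenotypeMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[CenterCallSet]:
    """Three replicate call sets: truth plus independent flips and no-calls.

    Each genotype is, independently per center, replaced by one of the two
    other dosage values with probability ``center_error_rate`` and set
    missing with probability ``center_missing_rate``. Planted artifact
    sites (multi-allelic ALT, discordant ALT) perturb one center's site
    metadata so the consensus merger must exclude them.
    """
    if rng is None:
        rng = stage_rng(config.seed, "centers")
    callsets = []
    n, m = G.dosages.shape
    site_cols = ["variant_id", "chrom", "pos", "ref", "alt"]
    art_multi = list(getattr(config, "_artifact_multi_ids", []))
    art_mismatch = list(getattr(config, "_artifact_mismatch_ids", []))
    for center in ("center1", "center2", "center3"):
        dos = G.dosages.copy()
        if config.center_error_rate > 0:
            flip = rng.uniform(size=(n, m)) < config.center_error_rate
            flip &= dos != MISSING
            # move to one of the two other dosage values
            shift = rng.integers(1, 3, size=(n, m))
            dos = np.where(flip, (dos + shift) % 3, dos).astype(np.int8)
        if config.center_missing_rate > 0:
            miss = rng.uniform(size=(n, m)) < config.center_missing_rate
            dos[miss] = MISSING
        var = G.variants[site_cols].copy()
        if center == "center2":
            multi = var["variant_id"].isin(art_multi)
            var.loc[multi, "alt"] = var.loc[multi, "alt"] + ",T"
            mism = var["variant_id"].isin(art_mismatch)
            var.loc[mism, "alt"] = [
                "A" if a != "A" else "G" for a in var.loc[mism, "alt"]
            ]
        callsets.append(CenterCallSet(center, dos, list(G.individuals), var))
    return callsets


# ---------------------------------------------------------------------------
# whole-cohort orchestration
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A fully generated synthetic study."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    true_model: TrueModel
    center_callsets: list[CenterCallSet] = field(default_factory=list)


def generate_cohort(config: SimulationConfig | None = None) -> Cohort:
    """Run every generator stage and return the assembled study inputs."""
    if config is None:
        config = SimulationConfig()
    config.validate()
    freq_rng = stage_rng(config.seed, "frequencies")
    geno_rng = stage_rng(config.seed, "genotypes")

    freqs = simulate_allele_frequencies(config, rng=freq_rng)
    variants = _variant_table(config, geno_rng)
    cohorts = assign_cohorts(config)

    # designate the array SNP per locus and pin its frequency
    for locus in config.loci:
        if locus.array_snp is None:
            continue
        idx = variants.index[variants["gene"] == locus.gene]
        mid = idx[len(idx) // 2]
        variants.loc[mid, "is_array_snp"] = True
        freqs[mid] = locus.array_snp.maf
    G = simulate_genotypes(freqs, config, rng=geno_rng, variants=variants, cohorts=cohorts)

    model = plant_effects(G, config)
    maf = sample_maf(G.dosages)
    model.monomorphic_sites = list(G.variants.loc[maf == 0, "variant_id"])

    # pick artifact sites for the consensus stage (non-causal, polymorphic)
    art_rng = stage_rng(config.seed, "centers")
    n_art = config.n_artifact_multiallelic + config.n_artifact_alt_mismatch
    if n_art > 0:
        causal = set(model.causal_ids())
        pool = [
            v
            for v, f in zip(G.variant_ids, maf)
            if f > 0 and v not in causal
        ]
        chosen = list(art_rng.choice(pool, size=n_art, replace=False))
        model.artifact_multiallelic = chosen[: config.n_artifact_multiallelic]
        model.artifact_alt_mismatch = chosen[config.n_artifact_multiallelic:]
    config._artifact_multi_ids = model.artifact_multiallelic  # type: ignore[attr-defined]
    config._artifact_mismatch_ids = model.artifact_alt_mismatch  # type: ignore[attr-defined]

    covariates = simulate_covariates(config)
    phenos = simulate_phenotypes(G, model, config, covariates=covariates)
    callsets = simulate_center_callsets(G, config, rng=art_rng)
    return Cohort(config, G, phenos, model, callsets)
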