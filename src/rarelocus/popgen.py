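"""Site-frequency spectra, diversity estimators and variant classification.

All spectra are folded (minor-allele counts); projection to a smaller
chromosome count uses the expectation of the hypergeometric draw, so
projected counts are real-valued.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, DELETERIOUS, CONSEQUENCES, GenotypeMatrix


@dataclass
class SiteFrequencySpectrum:
    """Folded SFS: ``counts[i]`` sites with minor-allele count ``i+1``."""

    n_chromosomes: int
    counts: np.ndarray  # length floor(n/2), may be expectation-valued

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.n_chromosomes // 2,):
            raise ValueError(
                f"folded SFS for n={self.n_chromosomes} needs "
                f"{self.n_chromosomes // 2} bins, got {self.counts.shape}"
            )
        if (self.counts < -1e-9).any():
            raise ValueError("SFS counts must be non-negative")

    @property
    def total_sites(self) -> float:
        return float(self.counts.sum())

    def proportions(self) -> np.ndarray:
        t = self.total_sites
        return self.counts / t if t > 0 else self.counts


def compute_maf(dosages: np.ndarray) -> tuple[float, int, int]:
    """Folded (MAF, MAC, n_nonmissing) for one dosage vector.

    Raises on an all-missing site (MAF undefined).
    """
    d = np.asarray(dosages)
    valid = d != MISSING
    n = int(valid.sum())
    if n == 0:
        raise ValueError("all genotypes missing: MAF undefined")
    alt = int(d[valid].sum())
    mac = min(alt, 2 * n - alt)
    return mac / (2 * n), mac, n


def site_mac_counts(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (minor allele count, non-missing chromosome count)."""
    valid = G.dosages != MISSING
    alt = np.where(valid, G.dosages, 0).sum(0)
    two_n = 2 * valid.sum(0)
    mac = np.minimum(alt, two_n - alt)
    return mac, two_n


def compute_sfs(G: GenotypeMatrix, m: int | None = None) -> SiteFrequencySpectrum:
    """Folded SFS of segregating sites, at a common chromosome count.

    Sites with missing genotypes have fewer observed chromosomes; each such
    site's single-site spectrum is hypergeometrically projected down to the
    common target ``m`` (default: the minimum per-site non-missing
    chromosome count) before aggregation, so every site contributes at one
    shared sample size.
    """
    if G.n_variants == 0:
        n = m if m is not None else 2 * G.n_individuals
        return SiteFrequencySpectrum(n, np.zeros(n // 2))
    mac, two_n = site_mac_counts(G)
    seg = mac > 0
    if not seg.any():
        n = m if m is not None else int(two_n.min()) if two_n.size else 0
        return SiteFrequencySpectrum(n, np.zeros(n // 2))
    mac, two_n = mac[seg], two_n[seg]
    if m is None:
        m = int(two_n.min())
    if (two_n < m).any():
        raise ValueError("target chromosome count exceeds an observed site's count")
    counts = np.zeros(m // 2)
    uniform = (two_n == m).all()
    if uniform:
        binned = np.bincount(mac, minlength=m // 2 + 1)[1 : m // 2 + 1]
        counts[: len(binned)] += binned
    else:
        for c, n_s in zip(mac, two_n):
            if n_s == m:
                counts[min(c, m - c) - 1] += 1
            else:
                counts += _project_site(int(c), int(n_s), m)
    return SiteFrequencySpectrum(m, counts)


def _project_site(i: int, n: int, m: int) -> np.ndarray:
    """Expected folded single-site SFS of a count-``i``-of-``n`` site at ``m``."""
    j = np.arange(0, m + 1)
    pmf = stats.hypergeom.pmf(j, n, i, m)
    out = np.zeros(m // 2)
    for jj, p in zip(j, pmf):
        folded = min(jj, m - jj)
        if folded >= 1:
            out[folded - 1] += p
    return out


def project_sfs(sfs: SiteFrequencySpectrum, m: int) -> SiteFrequencySpectrum:
    """Hypergeometric down-projection of a folded SFS to ``m`` chromosomes.

    For each source minor count ``i`` the site's mass is distributed over
    the number of minor alleles drawn in ``m`` draws without replacement
    from ``n`` chromosomes; draws of 0 (or ``m``) minor alleles are lost
    (the site is monomorphic in the smaller sample) and the remainder is
    refolded.
    """
    n = sfs.n_chromosomes
    if m > n:
        raise ValueError(f"cannot project up: m={m} > n={n}")
    if m < 2:
        raise ValueError("target chromosome count must be >= 2")
    if m == n:
        return SiteFrequencySpectrum(n, sfs.counts.copy())
    out = np.zeros(m // 2)
    for i, c in enumerate(sfs.counts, start=1):
        if c == 0:
            continue
        out += c * _project_site(i, n, m)
    return SiteFrequencySpectrum(m, out)


# ---------------------------------------------------------------------------
# diversity estimators
# ---------------------------------------------------------------------------

def watterson_theta(S: int, L: float, n: int) -> float:
    """Watterson's per-bp theta: S / (a_n * L), a_n = sum_{i<n} 1/i."""
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    if L <= 0:
        raise ValueError("sequenced length must be positive")
    if S < 0 or S > L * n:
        raise ValueError(f"impossible segregating-site count S={S} for L={L}, n={n}")
    a = np.sum(1.0 / np.arange(1, n))
    return S / (a * L)


def pairwise_theta(G: GenotypeMatrix, L: float) -> float:
    """Mean pairwise difference per bp from folded genotype counts.

    Per site the unbiased estimator 2 c (n_s - c) / (n_s (n_s - 1)) with
    ``c`` the minor allele count and ``n_s`` the site's non-missing
    chromosome count; summed over sites and divided by ``L``.
    """
    if L <= 0:
        raise ValueError("sequenced length must be positive")
    if G.n_variants == 0:
        return 0.0
    mac, two_n = site_mac_counts(G)
    ok = two_n >= 2
    mac, two_n = mac[ok].astype(float), two_n[ok].astype(float)
    per_site = 2.0 * mac * (two_n - mac) / (two_n * (two_n - 1.0))
    return float(per_site.sum() / L)


# ---------------------------------------------------------------------------
# variant classification
# ---------------------------------------------------------------------------

RARE_MAF_DEFAULT = 0.01
GOLDILOCKS_LOW = 0.005
GOLDILOCKS_HIGH = 0.02


def classify_variants(
    annotations: pd.DataFrame,
    mafs: np.ndarray,
    macs: np.ndarray,
    rare_cutoff: float = RARE_MAF_DEFAULT,
) -> pd.DataFrame:
    """Frequency and functional classification of every variant.

    Classes are overlays, not a partition: a MAF-0.5% probably-damaging
    missense variant is simultaneously rare, Goldilocks and functional.
    Predicted-functional means nonsense or probably-damaging missense.
    """
    ann = annotations.reset_index(drop=True)
    unknown = sorted(set(ann["consequence"]) - set(CONSEQUENCES))
    if unknown:
        raise ValueError(f"unknown consequence classes: {unknown}")
    mafs = np.asarray(mafs, dtype=float)
    macs = np.asarray(macs)
    if not (len(ann) == mafs.size == macs.size):
        raise ValueError("annotations, MAFs and MACs must align")
    table = ann[["variant_id", "gene", "consequence"]].copy()
    table["maf"] = mafs
    table["mac"] = macs
    table["is_singleton"] = macs == 1
    table["is_doubleton"] = macs == 2
    table["is_rare"] = mafs < rare_cutoff
    table["is_goldilocks"] = (mafs >= GOLDILOCKS_LOW) & (mafs <= GOLDILOCKS_HIGH)
    table["is_common"] = mafs >= rare_cutoff
    table["is_functional"] = ann["consequence"].isin(DELETERIOUS).to_numpy()
    return table


def functional_rare_odds_ratio(
    table: pd.DataFrame, rare_cutoff: float | None = None
) -> tuple[float, tuple[float, float], bool]:
    """Odds ratio that predicted-functional variants are rare.

    2x2 of functional x rare with the Woolf log-OR 95% CI; zero cells get
    the Haldane-Anscombe 0.5 correction (flagged in the third return).
    """
    if rare_cutoff is not None:
        rare = table["maf"].to_numpy() < rare_cutoff
    else:
        rare = table["is_rare"].to_numpy()
    func = table["is_functional"].to_numpy()
    a = float(np.sum(func & rare))
    b = float(np.sum(func & ~rare))
    c = float(np.sum(~func & rare))
    d = float(np.sum(~func & ~rare))
    corrected = False
    if min(a, b, c, d) == 0:
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            raise ValueError("degenerate 2x2 table: an entire margin is zero")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) + np.array([-1.96, 1.96]) * se)
    return or_, (float(lo), float(hi)), corrected


def variants_per_bp(total_sites: int, regions: pd.DataFrame) -> int:
    """Sequenced bp per variant site, rounded to the nearest integer.

    ``regions`` may carry explicit ``length_bp`` or BED-style
    ``start``/``end`` columns.
    """
    if len(regions) == 0:
        raise ValueError("regions table is empty")
    if total_sites <= 0:
        raise ValueError("density undefined with zero variant sites")
    if "length_bp" in regions.columns:
        total_bp = float(regions["length_bp"].sum())
    else:
        total_bp = float((regions["end"] - regions["start"]).sum())
    return int(round(total_bp / total_sites))
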