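"""Reference-study bookkeeping constants for the Finnish 17-locus panel.

The package's reference scenario is a targeted re-sequencing study of 78
genes at 17 metabolic-trait GWAS loci in 6,123 Finnish cohort members
(4,447 population-cohort participants plus 836 controls and 840 type-2-
diabetes cases from a case-control arm). Summary bookkeeping numbers of
that design — targeted region sizes, validated site counts, the low-count
validation ledger inputs, and predicted-consequence tallies — are bundled
here so the worked examples and the acceptance computations can run without
external inputs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .qc import ValidationCounts

N_INDIVIDUALS = 6123
N_COHORT_A = 4447
N_CONTROLS = 836
N_CASES = 840
N_CHROMOSOMES = 2 * N_INDIVIDUALS

#: validated polymorphic sites analysed after the full validation ledger
N_ANALYSIS_VARIANTS = 1852

#: common SNPs (MAF > 1%) entering the T2D case-control scan
N_T2D_SCAN_SNPS = 442

#: total pooled single-variant + gene-level tests in the inventory
N_TESTS_TOTAL = 2096
N_TESTS_SINGLE = 1802
N_TESTS_GENE = 294

#: predicted-consequence tallies over the analysed variants
N_MISSENSE_PROBABLY = 213
N_NONSENSE = 23

#: low-count-site validation ledger inputs (sites seen in <= 3 individuals
#: and absent from the SNP database at study time)
VALIDATION_COUNTS = ValidationCounts(
    initial_sites=2221,
    attempted=1104,
    tripleton_sites=91,
    tripleton_validated=91,
    doubleton_sites=207,
    doubleton_validated=205,
    singleton_wga_only=336,
    singleton_refuted=49,
    singleton_not_covered=20,
    singleton_wga_artifact=35,
    homozygous_alt_reclassified=11,
    reincluded_dbsnp=72,
    retained_total_printed=663,
)


def load_panel() -> pd.DataFrame:
    """Targeted-locus table: locus, chromosome, region-of-interest kb,
    validated variant sites.
    """
    with resources.files("rarelocus.data").joinpath("loci_panel.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    df["length_bp"] = (df["roi_kb"] * 1000).round().astype(int)
    return df
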