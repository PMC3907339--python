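import numpy as np
import pandas as pd
import pytest

import rarelocus as rl


def make_variants(m, gene="GENE1", chrom="1", start=1000, consequence="missense_benign"):
    """Minimal variant metadata table for hand-built genotype matrices."""
    cons = [consequence] * m if isinstance(consequence, str) else list(consequence)
    return pd.DataFrame(
        {
            "variant_id": [f"{gene}:{chrom}:{start + 10 * j}" for j in range(m)],
            "chrom": chrom,
            "pos": [start + 10 * j for j in range(m)],
            "ref": "A",
            "alt": "C",
            "gene": gene,
            "consequence": cons,
            "is_array_snp": False,
        }
    )


def make_matrix(dosages, **kw):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    return rl.GenotypeMatrix(
        dosages, [f"I{i:06d}" for i in range(n)], make_variants(m, **kw)
    )


@pytest.fixture(scope="session")
def small_config():
    return rl.SimulationConfig(
        n_individuals=500,
        seed=11,
        n_artifact_multiallelic=2,
        n_artifact_alt_mismatch=2,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return rl.generate_cohort(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
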