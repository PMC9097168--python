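import numpy as np
import pandas as pd
import pytest

from paleoqtl.synthio import SimConfig, gen_haplotypes, gen_variant_catalog, simulate


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulate-mode dataset shared across read-only tests."""
    return simulate(SimConfig(n_variants=600, n_haplotypes=200, seed=101))


@pytest.fixture(scope="session")
def small_catalog(small_sim):
    return small_sim.catalog


@pytest.fixture()
def tiny_panel():
    """Deterministic 4-variant panel with known LD structure."""
    from paleoqtl.ld import HaplotypePanel

    matrix = np.array(
        [
            [1, 1, 0, 1],
            [1, 1, 1, 0],
            [0, 0, 1, 1],
            [0, 0, 0, 0],
        ],
        dtype=np.uint8,
    )
    return HaplotypePanel(
        matrix=matrix,
        chrom=np.array(["chr1"] * 4),
        pos=np.array([100, 200, 300, 400]),
        ids=np.array(["v1", "v2", "v3", "v4"]),
    )


def make_catalog_row(**overrides):
    """A catalog row that passes every derived-HF rule unless overridden."""
    row = {
        "chrom": "chr1", "pos": 1000, "rsid": "rs1", "ref": "A", "alt": "G",
        "ancestral_call": "from_apes", "ancestral_allele": "A",
        "af_global": 0.95,
        "af_AFR": 0.95, "af_AMR": 0.95, "af_EAS": 0.95, "af_EUR": 0.95, "af_SAS": 0.95,
        "gt_altai": "0/0", "gt_vindija": "0/0", "gt_denisova": "0/0",
        "dp_altai": 50, "dp_vindija": 40, "dp_denisova": 40,
    }
    row.update(overrides)
    return pd.Series(row)
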