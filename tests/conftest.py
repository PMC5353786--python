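import numpy as np
import pandas as pd
import pytest

from dremap.consensus import PROFILE_COLUMNS, SampleProfile
from dremap.synthetic import SyntheticConfig, generate_all


def make_profile(sample_id, total, rows):
    """rows: (chrom, pos, total_reads, meth_reads)."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "total_reads", "meth_reads"])
    df["strand"] = "+"
    return SampleProfile(sample_id, total, df[PROFILE_COLUMNS])


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset shared by read-only tests."""
    return generate_all(SyntheticConfig(seed=11, n_cpg=800, n_genes=120,
                                        n_haplotypes=600, n_panel_snps=150))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
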