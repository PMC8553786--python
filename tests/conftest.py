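import numpy as np
import pandas as pd
import pytest

from epiherit import synthetic


@pytest.fixture(scope="session")
def small_sim():
    """A small planted simulation shared by read-only tests."""
    cfg = synthetic.SimConfig(
        seed=11,
        n_dmrs={"transgenerational": 5, "intergenerational": 10, "F0_only": 30},
        background_sites_per_chrom=2000,
        n_genes=20,
        n_te={"LTR": 30, "LINE": 30, "SINE": 30},
        n_vm_iap=40,
        n_vm_iap_variable=6,
        n_imprinted=10,
    )
    return synthetic.simulate_methylomes(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_counts(rows):
    """Count DataFrame from (chrom, pos, mC, total) tuples."""
    return pd.DataFrame(rows, columns=["chrom", "pos", "mC", "total"])
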