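import numpy as np
import pytest

from locusdissect import load_hdac9_table
from locusdissect.synthetic_data import SimConfig


@pytest.fixture(scope="session")
def hdac9_records():
    """The packaged 36-SNP catalogue for the HDAC9/TWIST1 CAD locus."""
    return load_hdac9_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_cfg():
    """A compact simulated study used by the unit tests."""
    return SimConfig(
        n_samples_eqtl=200,
        n_samples_gwas=2_000,
        n_variants=12,
        ld_block_sizes=(4, 4, 4),
        causal_variant_index=5,
        n_genes=26,
        n_modules=2,
        module_size=10,
        seed=11,
    )
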