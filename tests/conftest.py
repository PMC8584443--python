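import os

# Nested small GEMMs thrash badly under multithreaded BLAS; pin to one
# thread before numpy is first imported.
for _v in (
    "OMP_NUM_THREADS",
    "OPENBLAS_NUM_THREADS",
    "MKL_NUM_THREADS",
    "NUMEXPR_NUM_THREADS",
):
    os.environ.setdefault(_v, "1")

import numpy as np
import pytest

from pepcaps.config import NetworkConfig
from pepcaps.features import Peptide, load_default_properties, standardize_properties


@pytest.fixture(scope="session")
def default_table():
    return load_default_properties()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_table(rng):
    """A random (but valid) standardized 20 x 100 property table."""
    return standardize_properties(rng.normal(0, 3, (20, 100)))


@pytest.fixture()
def random_peptides(rng):
    """20 random peptides of length 2-50 over the canonical alphabet."""
    from pepcaps.constants import AMINO_ACIDS

    peps = []
    for _ in range(20):
        L = int(rng.integers(2, 51))
        peps.append(Peptide("".join(rng.choice(list(AMINO_ACIDS), L))))
    return peps


@pytest.fixture()
def tiny_config():
    """Smallest config that exercises every architectural element."""
    return NetworkConfig(
        conv_channels=8, cbam_reduction=2, caps_dim=4, out_caps_dim=8, seed=7
    )
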