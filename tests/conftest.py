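import numpy as np
import pytest

from fncinterp.fnc_data import FNCSample
from fncinterp.synthetic import (ContinuumSpec, build_block_prototype,
                                 domain_blocks)

#: Small 5-domain layout (C=12) used where full 53-component matrices would
#: only slow tests down without changing what they check.
SMALL_SIZES = {"SC": 2, "SM": 3, "VI": 3, "CC": 2, "CB": 2}


@pytest.fixture(scope="session")
def small_prototypes():
    return (build_block_prototype("control", SMALL_SIZES),
            build_block_prototype("patient", SMALL_SIZES))


@pytest.fixture(scope="session")
def small_spec(small_prototypes):
    pc, pp = small_prototypes
    return ContinuumSpec(n_per_group=30, base_fnc_control=pc,
                         base_fnc_patient=pp, edge_noise_sd=0.05)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_symmetric(rng, c, scale=0.5):
    m = rng.uniform(-scale, scale, size=(c, c))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    return m


@pytest.fixture
def random_corr_sample(rng):
    """A valid random 8x8 correlation FNC sample."""
    a = rng.standard_normal((40, 8))
    m = np.corrcoef(a, rowvar=False)
    np.fill_diagonal(m, 1.0)
    return FNCSample(subject_id="s0", matrix=m)
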