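import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))

from pvleak import FluidProperties, HemodynamicContext, synthetic


@pytest.fixture(scope="session")
def die_stack():
    """The verification annular die: R_i=10 mm, R_o=11 mm, L=30 mm."""
    return synthetic.make_annular_die(10e-3, 11e-3, 30e-3, n_theta=64, n_slices=16)


@pytest.fixture(scope="session")
def blood():
    return FluidProperties()


@pytest.fixture(scope="session")
def hemo():
    return HemodynamicContext()


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
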