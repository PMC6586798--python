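import numpy as np
import pytest

from nucleokit.library import builtin_enzymes, builtin_substrates, enzyme_for_simulation
from nucleokit.simulate import DyeModel, SimConfig


@pytest.fixture(scope="session")
def subs():
    return builtin_substrates()


@pytest.fixture(scope="session")
def exo3():
    return enzyme_for_simulation("ExoIII")


@pytest.fixture(scope="session")
def t7():
    return enzyme_for_simulation("T7 Exo")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_dye():
    """Noise-free, bleach-free dye for exact algebraic checks."""
    return DyeModel(bleach_rate=0.0)


def make_config(substrate, enzyme=None, conc=0.0, **kw):
    kw.setdefault("noise_sd", 0.0)
    return SimConfig(substrate=substrate, enzyme=enzyme, enzyme_conc=conc, **kw)
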