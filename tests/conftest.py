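import numpy as np
import pytest

from epgan import datagen as dg
from epgan import hh_core as hh
from epgan import protocols as pr


@pytest.fixture(scope="session")
def registry():
    return hh.load_registry()


@pytest.fixture(scope="session")
def space_small(registry):
    return hh.build_parameter_space("small", registry)


@pytest.fixture(scope="session")
def space_large(registry):
    return hh.build_parameter_space("large", registry)


@pytest.fixture(scope="session")
def default_params(space_large):
    return hh.assemble_parameter_vector(space_large)


def make_leak_only(space, g_leak=1.0, e_leak=-70.0, c_m=4.0, v0=-70.0):
    """All conductances zero except the ohmic leak: an RC membrane."""
    vals = {f"{c.name}_g": 0.0 for c in space.registry.channels}
    vals.update(Leak_g=g_leak, E_L=e_leak, C_m=c_m, V_0=v0)
    return hh.assemble_parameter_vector(space, vals)


@pytest.fixture(scope="session")
def leak_params(space_small):
    return make_leak_only(space_small)


@pytest.fixture(scope="session")
def tiny_corpus(space_small):
    """Six constraint-satisfying records (two per response class), seeded."""
    return dg.generate_dataset(6, space_small, rng=123)


@pytest.fixture(scope="session")
def windowed_example(tiny_corpus):
    return tiny_corpus[0].windowed


@pytest.fixture(scope="session")
def cc_protocol():
    return pr.get_preset("simulated_cc")


@pytest.fixture(scope="session")
def vc_protocol():
    return pr.get_preset("simulated_vc")
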