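import numpy as np
import pytest

from pentitol.geometry import AlditolTopology, GeometryParams, PHI_NAMES, build_conformer


@pytest.fixture(scope="session")
def ribitol():
    return AlditolTopology.from_name("ribitol")


@pytest.fixture(scope="session")
def d_arabitol():
    return AlditolTopology.from_name("d-arabitol")


@pytest.fixture(scope="session")
def xylitol():
    return AlditolTopology.from_name("xylitol")


@pytest.fixture(scope="session")
def params():
    return GeometryParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20240229)


def make_conformer(topology, phis, **kw):
    return build_conformer(topology, dict(zip(PHI_NAMES, phis)), **kw)
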