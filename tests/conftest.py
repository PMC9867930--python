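import numpy as np
import pytest

from macudev import (
    AnnulusSpec,
    compose_gcipl,
    default_gcl_model,
    default_ipl_model,
    desk_geometry,
)


@pytest.fixture(scope="session")
def geom64():
    return desk_geometry(64)


@pytest.fixture(scope="session")
def models64(geom64):
    gcl = default_gcl_model(geom64)
    ipl = default_ipl_model(geom64)
    return {"gcl": gcl, "ipl": ipl, "gcipl": compose_gcipl(gcl, ipl)}


@pytest.fixture(scope="session")
def annulus64(geom64):
    return AnnulusSpec(center_px=geom64.fovea_px)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
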