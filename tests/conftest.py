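import numpy as np
import pytest

from protodyn import beam_physics as bp


@pytest.fixture(scope="session")
def water():
    return bp.MEDIA["water"]


@pytest.fixture(scope="session")
def dmso():
    return bp.MEDIA["DMSO"]


@pytest.fixture(scope="session")
def beam_12p5():
    return bp.ProtonBeam(12.5)


@pytest.fixture(scope="session")
def dmso_curve(beam_12p5, dmso):
    grid = np.arange(0.0, 3.0, 0.005)
    return bp.depth_dose(beam_12p5, dmso, grid)
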