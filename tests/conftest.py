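import numpy as np
import pytest

from arcqa.detector_geometry import PhantomModel, build_layout
from arcqa.synthetic_dose import BeamModel


@pytest.fixture(scope="session")
def layout():
    return build_layout()


@pytest.fixture(scope="session")
def phantom():
    return PhantomModel(plug_present=False)


@pytest.fixture(scope="session")
def phantom_with_plug():
    return PhantomModel(plug_present=True)


@pytest.fixture(scope="session")
def beam_6x():
    return BeamModel.for_energy("6X")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
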