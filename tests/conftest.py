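import numpy as np
import pytest

from drivewave import DemographyParams, DriveParams, Grid1D, Model

ALL_MODELS = [Model.BN, Model.BA, Model.DN, Model.DA]


def make_demo(model, r, a=-0.5):
    """Demography with a default Allee threshold where one is required."""
    model = Model(model)
    return DemographyParams(model=model, r=r, a=a if model.has_allee else None)


@pytest.fixture
def reference_drive():
    """The drive construct used throughout the regime figures: c=0.85, h=0.9."""
    return DriveParams(s=0.2, c=0.85, h=0.9)


@pytest.fixture
def small_grid():
    return Grid1D(L=60, dx=1.0, dt=1.0 / 6.0, T=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
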