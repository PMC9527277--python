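import numpy as np
import pytest

from camvitals import colorimetry, synthetic
from camvitals.forward_model import build_training_set
from camvitals.inverse_mapping import fit_m2


@pytest.fixture(scope="session")
def training_small():
    """Small Monte-Carlo training set for unit-level regression tests."""
    return build_training_set(n=60, photons=3000, seed=7)


@pytest.fixture(scope="session")
def m2_small(training_small):
    return fit_m2(training_small, order=2)


@pytest.fixture(scope="session")
def camera():
    return synthetic.SyntheticCamera()


@pytest.fixture(scope="session")
def checker(camera):
    return synthetic.make_color_checker(camera)


@pytest.fixture(scope="session")
def m1(checker):
    return colorimetry.fit_m1(checker)


@pytest.fixture(scope="session")
def emulator_small():
    """Reflectance emulator at the default scenario melanin fraction."""
    return synthetic.ReflectanceEmulator(cm=0.04, photons=30_000, seed=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
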