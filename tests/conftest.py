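import numpy as np
import pytest

from slitfundus.optics import FundusLens
from slitfundus.synthetic import generate_phantom


@pytest.fixture(scope="session")
def phantom256():
    return generate_phantom(1, size=(256, 256))


@pytest.fixture(scope="session")
def phantom512():
    return generate_phantom(3, size=(512, 512))


@pytest.fixture(scope="session")
def lens90():
    return FundusLens(90)


@pytest.fixture(scope="session")
def lens60():
    return FundusLens(60)


@pytest.fixture(scope="session")
def lens40():
    return FundusLens(40)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
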