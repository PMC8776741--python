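import numpy as np
import pytest

import imksurv as ik


@pytest.fixture(scope="session")
def ctx():
    """150 kVp X-ray microdosimetric context (gamma ~ 0.9547 Gy)."""
    return ik.REFERENCE_CONTEXT


@pytest.fixture(scope="session")
def gamma(ctx):
    return ik.gamma_coefficient(ctx)


@pytest.fixture(scope="session")
def sas_progeny():
    """Parental progeny population of the SAS family."""
    return ik.PopulationParams(alpha0=0.208, beta0=0.044, repair_rate=1.279)


@pytest.fixture(scope="session")
def sas_family():
    return ik.SAS_FAMILY


@pytest.fixture(scope="session")
def hsc2_family():
    return ik.HSC2_FAMILY


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
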