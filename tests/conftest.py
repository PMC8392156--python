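import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import oilspec as o

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def grids():
    return o.default_grids()


@pytest.fixture(scope="session")
def library():
    return o.make_endmember_library(1)


@pytest.fixture(scope="session")
def mexican_design():
    return o.build_design_mexican()


@pytest.fixture(scope="session")
def kenyan_design():
    return o.build_design_kenyan()


@pytest.fixture(scope="session")
def mexican_dataset(mexican_design, library):
    """Full Mexican-design synthetic dataset (570 spectra per modality)."""
    return o.generate_dataset(mexican_design, library, noise=o.default_noise(1))


@pytest.fixture(scope="session")
def kenyan_dataset(kenyan_design, library):
    return o.generate_dataset(kenyan_design, library, noise=o.default_noise(1))


@pytest.fixture(scope="session")
def labelled_fused(mexican_dataset):
    """Balanced 1125-row 5-class set on fused spectra."""
    return o.assemble_classification_set(mexican_dataset, modality="fused", seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
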