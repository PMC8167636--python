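import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from splintfea.geometry import DentitionSpec, build_dentition
from splintfea.io import packaged_measurements
from splintfea.meshing import mesh_dentition
from splintfea.occlusal import OcclusalMeasurement

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def measurements():
    """The three packaged clinical T-Scan acquisitions."""
    return packaged_measurements()


@pytest.fixture(scope="session")
def toy_spec():
    """Three-tooth arch used for fast solver-level scenario tests."""
    return DentitionSpec(n_teeth=3)


@pytest.fixture(scope="session")
def toy_measurement():
    return OcclusalMeasurement("toy", 2000, {32: 40.0, 31: 35.0, 41: 25.0})


@pytest.fixture(scope="session")
def toy_dentition(toy_spec):
    return build_dentition(toy_spec, with_splint=False)


@pytest.fixture(scope="session")
def toy_dentition_splinted(toy_spec):
    return build_dentition(toy_spec, with_splint=True)


@pytest.fixture(scope="session")
def toy_model(toy_dentition):
    return mesh_dentition(toy_dentition)


@pytest.fixture(scope="session")
def toy_model_splinted(toy_dentition_splinted):
    return mesh_dentition(toy_dentition_splinted)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
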