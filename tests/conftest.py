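import pytest
from hypothesis import settings

import semdecode as sd

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_geometry():
    return sd.VolumeGeometry.isotropic((10, 10, 10), 3.0)


@pytest.fixture(scope="session")
def shared_region(small_geometry):
    return sd.cuboid_region(
        small_geometry, (2, 2, 2), (7, 7, 7), "shared_semantic", amplitude=2.0, name="A"
    )


@pytest.fixture(scope="session")
def noise_free_dataset(small_geometry, shared_region):
    cfg = sd.SimulationConfig(
        n_subjects=2, tasks=("naming", "reading"), n_runs=3, n_concepts=4,
        presentations_per_run=2, effect_regions=(shared_region,), noise_sd=0.0, seed=11,
    )
    return sd.generate_beta_dataset(cfg, small_geometry)


@pytest.fixture(scope="session")
def signal_free_dataset(small_geometry):
    cfg = sd.SimulationConfig(
        n_subjects=3, tasks=("reading",), n_runs=5, n_concepts=10,
        noise_sd=1.0, seed=12,
    )
    return sd.generate_beta_dataset(cfg, small_geometry)


@pytest.fixture(scope="session")
def cross_language_reading():
    return sd.make_cross_language_scheme("reading", n_runs=5)
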