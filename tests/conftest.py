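import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from m15tg43.dose_engine import load_reference_tables
from m15tg43.mc_transport import TallyGridSpec, simulate_water
from m15tg43.physics_data import load_material, load_spectrum
from m15tg43.source_model import build_m15


@pytest.fixture(scope="session")
def spectrum():
    return load_spectrum()


@pytest.fixture(scope="session")
def geometry():
    return build_m15()


@pytest.fixture(scope="session")
def water():
    return load_material("water")


@pytest.fixture(scope="session")
def reference():
    return load_reference_tables()


@pytest.fixture(scope="session")
def small_grid_spec():
    """Coarse polar grid spanning both poles, cheap enough for unit tests."""
    return TallyGridSpec(np.array([0.5, 1.0, 2.0, 5.0]),
                         np.array([0.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0]))


@pytest.fixture(scope="session")
def small_water_grid(geometry, spectrum, small_grid_spec):
    """A shared 2e5-history water tally used by several statistical checks."""
    return simulate_water(geometry, spectrum, small_grid_spec,
                          n_histories=2 * 10**5, seed=2024, n_batches=20)
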