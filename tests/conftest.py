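import numpy as np
import pytest

from densestorm.localization_io import LocalizationTable
from densestorm.simulator import generate_filaments, simulate_localizations


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_table(rng):
    """200 random localizations over a 1000 nm field, 100 frames."""
    n = 200
    return LocalizationTable(
        x=rng.uniform(0, 1000, n),
        y=rng.uniform(0, 1000, n),
        frame=rng.integers(0, 100, n),
        photons=rng.exponential(2000, n),
        precision=np.full(n, 10.0),
    )


@pytest.fixture(scope="session")
def filament_dataset():
    """A small simulated filament scene with its localization table."""
    rng = np.random.default_rng(7)
    scene = generate_filaments(6, 3000, rng=rng)
    locs = simulate_localizations(scene, rng)
    return scene, locs
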