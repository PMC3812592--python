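import numpy as np
import pytest

from grasspec.spectra_io import ReadingSet, SpectralDataset, Spectrum
from grasspec.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def grid_1nm():
    return np.arange(350.0, 2501.0)


@pytest.fixture
def flat_spectrum():
    wl = np.arange(1000.0, 1101.0)
    return Spectrum(wl, np.full(wl.size, 0.4))


@pytest.fixture
def small_dataset(rng):
    """5 samples x 40 bands of positive pseudo-reflectance."""
    wl = np.linspace(400.0, 800.0, 40)
    X = 0.3 + 0.1 * rng.random((5, 40))
    return SpectralDataset(wl, X, tuple(f"p{i}" for i in range(5)))


@pytest.fixture(scope="session")
def tiny_simulation():
    """6 plots x 4 readings, fixed seed; shared across tests (read-only)."""
    cfg = SimulationConfig(n_plots=6, readings_per_plot=4, seed=7)
    return cfg, simulate_dataset(cfg)


def make_reading_set(plot_id, wl, rows):
    return ReadingSet(plot_id, tuple(Spectrum(wl, r) for r in rows))
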