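import numpy as np
import pytest

import lipidir as L


@pytest.fixture(scope="session")
def grid():
    """Default 4000-500 cm^-1 grid at 2 cm^-1 (1751 channels, descending)."""
    return L.default_grid()


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated screen (4 strains, 2 bio x 2 tech reps) shared by
    read-only tests."""
    sset, ref, truth = L.simulate_study(seed=11, n_strains=4, tech_reps=2)
    return sset, ref, truth


@pytest.fixture(scope="session")
def default_sim():
    """The full default screening design (13 x 4 x 2 x 3 = 312 spectra)."""
    sset, ref, truth = L.simulate_study(seed=1)
    return sset, ref, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_set(wavenumbers, absorbance, n_strains=None):
    """Build a SpectrumSet with auto-generated metadata (one strain, one
    substrate, samples as successive technical replicates)."""
    absorbance = np.atleast_2d(absorbance)
    samples = [
        L.SampleMeta(f"s{i}", "S01", "G", 1, i + 1)
        for i in range(absorbance.shape[0])
    ]
    return L.SpectrumSet(np.asarray(wavenumbers, float), absorbance, samples)
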