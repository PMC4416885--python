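import numpy as np
import pytest

from irhisto.metrics import compute_features, default_metric_library
from irhisto.preprocess import preprocess_cube
from irhisto.spectral_io import WavenumberAxis
from irhisto.synthetic_data import PhantomSpec, default_class_library, synth_phantom


@pytest.fixture(scope="session")
def axis():
    return WavenumberAxis.regular()


@pytest.fixture(scope="session")
def library():
    return default_class_library()


@pytest.fixture(scope="session")
def metric_defs():
    return default_metric_library()


@pytest.fixture(scope="session")
def small_phantom():
    """64x64 layered-biopsy phantom at default (SNR 500) conditions."""
    spec = PhantomSpec(rows=64, cols=64, seed=7, lymph_focus_radius=3)
    return synth_phantom(spec)


@pytest.fixture(scope="session")
def small_features(small_phantom, metric_defs):
    cube, truth = small_phantom
    processed, mask, _ = preprocess_cube(cube)
    return compute_features(processed, mask, metric_defs), truth


def random_spectra(axis, n, rng, noise_sd=5e-4):
    """Random multi-peak synthetic spectra for oracle-equivalence checks."""
    v = axis.values
    spectra = np.zeros((n, v.size))
    for i in range(n):
        n_peaks = rng.integers(4, 9)
        centers = rng.uniform(950, 1750, n_peaks)
        heights = rng.uniform(0.05, 1.0, n_peaks)
        fwhms = rng.uniform(15, 60, n_peaks)
        for c, h, f in zip(centers, heights, fwhms):
            spectra[i] += h * np.exp(-4 * np.log(2) * ((v - c) / f) ** 2)
        spectra[i] += 1.0 * np.exp(-4 * np.log(2) * ((v - 1652) / 25) ** 2)
        spectra[i] += rng.uniform(-2e-5, 2e-5) * (v - v[0])
        spectra[i] += rng.normal(0, noise_sd, v.size)
    return spectra
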