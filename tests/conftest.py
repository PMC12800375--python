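import numpy as np
import pytest

from matsne import (
    HistogramElement,
    PlantedDesign,
    make_histogram_data,
    make_scalar_data,
    make_series_data,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scalar_data():
    """Planted 2×2-group scalar dataset, 10×8, clear separation."""
    design = PlantedDesign.balanced(10, 8, 2, 2, separation=10.0, noise_sd=1.0, seed=3)
    data, design = make_scalar_data(design)
    return data, design


@pytest.fixture
def small_series_data():
    design = PlantedDesign.balanced(4, 4, 2, 2, separation=3.0, noise_sd=0.2, seed=5)
    data, design = make_series_data(design, T=12, P=2)
    return data, design


@pytest.fixture
def small_histogram_data():
    design = PlantedDesign.balanced(4, 4, 2, 2, separation=4.0, noise_sd=1.0, seed=7)
    data, design = make_histogram_data(design, B=12, n_samples=300)
    return data, design


def random_histogram(rng, n_bins=None, lo=-2.0, span=4.0):
    """A random histogram with strictly positive masses (no quantile jumps)."""
    if n_bins is None:
        n_bins = int(rng.integers(2, 8))
    start = lo + rng.uniform(0, 1)
    widths = rng.uniform(0.2, 1.5, size=n_bins)
    edges = start + np.concatenate(([0.0], np.cumsum(widths)))
    masses = rng.uniform(0.05, 1.0, size=n_bins)
    masses = masses / masses.sum()
    return HistogramElement(edges, masses)
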