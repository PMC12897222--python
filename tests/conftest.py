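"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from grainspec import SynthConfig, WavelengthGrid, generate_spectra


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return WavelengthGrid.default(n_bands=32)


@pytest.fixture
def planted_small():
    """100 samples x 30 bands with two single-band class effects (5, 20)."""
    cfg = SynthConfig(n_healthy=40, n_infested=60, n_bands=30,
                      seed=42).with_planted_bands([5, 20], amplitude=0.02)
    matrix, truth = generate_spectra(cfg)
    return matrix, truth


@pytest.fixture
def clean_small():
    """Noise-free, scatter-free spectra: class difference only."""
    cfg = SynthConfig(n_healthy=20, n_infested=30, n_bands=40, seed=7,
                      gain_sd=0.0, offset_sd=0.0, baseline_sd=0.0,
                      noise_sd=0.0)
    matrix, truth = generate_spectra(cfg)
    return matrix, truth
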