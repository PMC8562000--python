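"""Shared fixtures: phantoms are expensive, so they are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from octamacula.preprocess import run_preprocess
from octamacula.synthgen import PhantomParams, generate_phantom

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def phantom_default():
    """Full-size phantom at default (realistic) noise, target VAD 0.32."""
    params = PhantomParams(rng_seed=11, target_vad=0.32)
    angio, truth = generate_phantom(params)
    return params, angio, truth


@pytest.fixture(scope="session")
def phantom_clean():
    """Full-size phantom with zero noise and no illumination gradient."""
    params = PhantomParams(
        rng_seed=7, target_vad=0.32, noise_sigma=0.0, faz_noise_level=0.0,
        illumination_gradient_amp=0.0,
    )
    angio, truth = generate_phantom(params)
    return params, angio, truth


@pytest.fixture(scope="session")
def vesselness_clean(phantom_clean):
    """Vesselness map of the clean phantom through the default chain."""
    _, angio, _ = phantom_clean
    return run_preprocess(angio.pixels)


@pytest.fixture(scope="session")
def small_phantom():
    """Quick 128-px phantom for cheap structural tests."""
    params = PhantomParams(image_side_px=128, rng_seed=3, target_vad=0.30)
    angio, truth = generate_phantom(params)
    return params, angio, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
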