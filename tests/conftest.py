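"""Shared fixtures: synthetic trials at the reference walking condition.

Heavy trials are session-scoped; tests must not mutate them in place
(use ``.copy()``).
"""

from dataclasses import replace

import pytest

from ovigait.markers import LandmarkMap
from ovigait.synthetic import (SyntheticGaitConfig, default_reference_config,
                               synthesize_trial)


@pytest.fixture(scope="session")
def lmap():
    return LandmarkMap.default()


@pytest.fixture(scope="session")
def ref_config():
    """Reference walking condition: 20 cycles, 1 mm marker noise, seed 42."""
    return default_reference_config()


@pytest.fixture(scope="session")
def ref_trial(ref_config):
    """(marker set, ground truth) at the reference condition."""
    return synthesize_trial(ref_config)


@pytest.fixture(scope="session")
def clean_config(ref_config):
    return replace(ref_config, marker_noise_sd=0.0, n_cycles=10)


@pytest.fixture(scope="session")
def clean_trial(clean_config):
    """Noise-free reference trial (10 cycles)."""
    return synthesize_trial(clean_config)


@pytest.fixture(scope="session")
def aligned_config():
    """Timing chosen so every contact boundary falls on a frame: cycle 0.6 s
    at 100 Hz with duty factor 0.6 (stance exactly 36 frames)."""
    return SyntheticGaitConfig(cycle_time=0.6, duty_factor=0.6,
                               marker_noise_sd=0.0, n_cycles=10)


@pytest.fixture(scope="session")
def aligned_trial(aligned_config):
    return synthesize_trial(aligned_config)
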