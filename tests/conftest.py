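"""Shared fixtures: small simulated recordings reused across test modules."""

import numpy as np
import pytest

from focidyn import registration as reg
from focidyn.synthetic import SimulationConfig, simulate_nucleus


@pytest.fixture(scope="session")
def clean_alpha():
    """Zero-noise, zero-drift alpha-like recording without interactions."""
    cfg = SimulationConfig(condition="alpha", seed=7, shot_noise=False,
                           read_noise_sd=0.0, merge_rate=0.0, split_rate=0.0)
    stack, truth = simulate_nucleus(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def drifting_alpha():
    """Noisy alpha-like recording with rigid nuclear drift."""
    cfg = SimulationConfig(condition="alpha", seed=5,
                           drift_per_frame=(0.35, -0.22, 0.25),
                           merge_rate=0.0, split_rate=0.0)
    stack, truth = simulate_nucleus(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def registered_drifting_alpha(drifting_alpha):
    """Estimated transforms and registered stack for the drifting recording."""
    cfg, stack, truth = drifting_alpha
    transforms = reg.estimate_rigid(stack)
    registered = reg.apply_rigid(stack, transforms)
    return cfg, stack, truth, transforms, registered


@pytest.fixture(scope="session")
def frozen_drifting():
    """Zero-noise recording with frozen foci and pure rigid drift.

    With Dc = 0 the only frame-to-frame change is the drift itself, so
    registration estimates can be compared against the schedule exactly.
    """
    cfg = SimulationConfig(condition="alpha", seed=3, shot_noise=False,
                           read_noise_sd=0.0, merge_rate=0.0, split_rate=0.0,
                           Dc_true=1e-9, n_frames=30, initial_foci=10,
                           focus_birth_rate=0.0, focus_lifetime_mean=np.inf,
                           drift_per_frame=(0.4, -0.3, 0.3))
    stack, truth = simulate_nucleus(cfg)
    return cfg, stack, truth
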