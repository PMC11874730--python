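"""Shared fixtures: small trajectories, phantom sessions, and the trained
desk-scale model (session-scoped; training runs once per test session)."""

import numpy as np
import pytest

from spiralcine.phantom import PhantomConfig, simulate_session
from spiralcine.trajectory import design_spiral


@pytest.fixture(scope="session")
def small_traj():
    """Tiny 5-arm spiral on a 16-pixel grid for exact-DFT comparisons."""
    return design_spiral(fov_mm=16.0, resolution_mm=1.0, n_arms=5,
                         n_samples=40, matrix=16)


@pytest.fixture(scope="session")
def desk_traj():
    """The 13-arm desk-scale spiral (64-pixel grid, 4 mm pixels)."""
    return design_spiral(fov_mm=256.0, resolution_mm=4.0, n_arms=13,
                         n_samples=256, matrix=64)


@pytest.fixture(scope="session")
def desk_config():
    return PhantomConfig(grid=64, pixel_mm=4.0, seed=3)


@pytest.fixture(scope="session")
def breathhold_session(desk_config):
    """10 s regular-rhythm breath-hold session (8 pattern orientations)."""
    return simulate_session(desk_config, mode="breathhold", duration_s=10.0)


@pytest.fixture(scope="session")
def arrhythmic_session():
    """12 s session with lognormal RR variability for gating tests."""
    cfg = PhantomConfig(grid=64, pixel_mm=4.0, seed=11, rr_variability=0.12)
    return simulate_session(cfg, mode="breathhold", duration_s=12.0)


@pytest.fixture(scope="session")
def trained_desk_model():
    """The 30-epoch desk-scale training experiment (seed pinned).

    Session-scoped because it is by far the most expensive fixture; the
    training-quality and EF-from-model tests share one run.
    """
    from spiralcine.experiments import run_desk_training
    model, result, val_data = run_desk_training(seed=0, epochs=30)
    return model, result, val_data
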