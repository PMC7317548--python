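"""Shared fixtures: small-scale phantoms and reconstructions.

Expensive end-to-end objects are session-scoped and reused across test
modules; they run at reduced grid sizes that preserve the physical
geometry (the phantom is defined in millimetres).
"""

from __future__ import annotations

import pytest

from adaptspect import (
    AcquisitionConfig,
    AdaptiveConfig,
    DetectConfig,
    ExperimentConfig,
    Grid3D,
    PhantomConfig,
    ReconConfig,
    SystemModel,
    body_tracing_orbit,
    forward_project,
    make_phantom,
)


@pytest.fixture(scope="session")
def half_grid() -> Grid3D:
    """Half-scale grid: 64 cube, 7.8-mm voxels (same 500-mm field of view)."""
    return Grid3D((64, 64, 64), 7.8)


@pytest.fixture(scope="session")
def reference_phantom(half_grid):
    """Reference configuration phantom on the half-scale grid."""
    return make_phantom(PhantomConfig(), half_grid)


@pytest.fixture(scope="session")
def small_acq() -> AcquisitionConfig:
    """Acquisition with a reduced angle count (32, divisible by 8 subsets)."""
    return AcquisitionConfig(n_angles=32)


@pytest.fixture(scope="session")
def reference_model(reference_phantom, half_grid, small_acq):
    """Orbit + system model for the reference phantom, built once."""
    _, mu, masks = reference_phantom
    orbit = body_tracing_orbit(masks.body, half_grid, small_acq.gap_mm, small_acq.n_angles)
    return orbit, SystemModel(mu, orbit, small_acq)


@pytest.fixture(scope="session")
def noiseless_projection(reference_phantom, reference_model, small_acq):
    """Noise-free 1-min expected projections of the reference phantom."""
    activity, mu, _ = reference_phantom
    orbit, model = reference_model
    return forward_project(activity, mu, orbit, small_acq, 1.0, model=model)


@pytest.fixture(scope="session")
def noiseless_reconstruction(noiseless_projection, reference_phantom, small_acq, reference_model):
    """OSEM reconstruction of the noise-free reference projections."""
    from adaptspect import osem_reconstruct

    _, mu, _ = reference_phantom
    _, model = reference_model
    return osem_reconstruct(noiseless_projection, mu, small_acq, ReconConfig(), model=model)


@pytest.fixture(scope="session")
def tiny_experiment(half_grid) -> ExperimentConfig:
    """A fast adaptive-scan experiment for behavioural (not quantitative) tests."""
    return ExperimentConfig(
        grid=half_grid,
        acquisition=AcquisitionConfig(n_angles=32, max_rotations=6),
        detect=DetectConfig(),
        adaptive=AdaptiveConfig(max_rotations=6),
    )
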