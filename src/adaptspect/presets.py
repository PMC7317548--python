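"""Frozen study presets.

``study_experiment`` returns the experiment configuration used by the
packaged simulation study: the Table-style deposition sweep phantom at a
3/4-scale grid (96 cube, 5.2-mm voxels, 96 view angles) with the count
calibration frozen after a one-off tuning of the system sensitivity against
the published termination-time table (see docs/methods.md).  All other
acquisition, reconstruction, detection and stopping parameters are the
clinical protocol values.
"""

from __future__ import annotations

from dataclasses import replace

from .acquisition import AcquisitionConfig
from .experiments import ExperimentConfig
from .grids import Grid3D
from .phantom import PhantomConfig

__all__ = ["STUDY_SENSITIVITY", "study_experiment"]

# Frozen count calibration: expected photopeak counts/s/MBq of in-air
# activity for the simulated dual-head LEHR system at study scale.
STUDY_SENSITIVITY = 46.0


def study_experiment(
    base_seed: int = 0,
    dep_concentration: float = 0.10,
    **phantom_overrides,
) -> ExperimentConfig:
    """The frozen simulation-study configuration.

    Parameters other than the deposition properties and the seed are not
    meant to be varied; they define the study conditions.
    """
    phantom = replace(
        PhantomConfig(), dep_concentration=dep_concentration, **phantom_overrides
    )
    return ExperimentConfig(
        phantom=phantom,
        grid=Grid3D((96, 96, 96), 5.2),
        acquisition=AcquisitionConfig(n_angles=96, sensitivity=STUDY_SENSITIVITY),
        base_seed=base_seed,
    )
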