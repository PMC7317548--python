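"""Automatic extrahepatic deposition detection.

Pipeline on a reconstructed volume: (1) restrict to the background — the
body with the liver and lung masks removed after dilating them by 2 cm to
absorb partial-volume spill and breathing motion; (2) keep voxels whose
activity concentration exceeds 0.017% of the injected activity per ml;
(3) merge surviving voxels into 3D clusters (26-connectivity); (4) keep
clusters whose summed reconstructed activity exceeds 0.1% of the total
reconstructed activity.  Both thresholds are strict (">"), and note the
asymmetry: the voxel threshold is relative to the *injected* activity while
the cluster threshold is relative to the *total reconstructed* activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import Grid3D, OrganMasks
from .reconstruction import Reconstruction

__all__ = [
    "DetectConfig",
    "Deposition",
    "dilate_mask",
    "background_region",
    "detect_depositions",
]

# 26-neighbourhood in 3D
_STRUCTURE = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class DetectConfig:
    dilation_radius: float = 20.0  # mm
    concentration_threshold_frac: float = 1.7e-4  # of injected activity, per ml
    cluster_activity_frac: float = 1.0e-3  # of total reconstructed activity
    connectivity: int = 26

    def __post_init__(self) -> None:
        for name in (
            "dilation_radius",
            "concentration_threshold_frac",
            "cluster_activity_frac",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class Deposition:
    """One detected extrahepatic cluster."""

    mask: np.ndarray = field(repr=False)
    activity: float = 0.0  # MBq, summed reconstructed activity in the mask
    centroid: tuple[float, float, float] = (0.0, 0.0, 0.0)  # voxel coords

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _ball_structure(radius_vox: int) -> np.ndarray:
    r = int(radius_vox)
    if r < 1:
        return np.ones((1, 1, 1), dtype=bool)
    g = np.arange(-r, r + 1)
    x, y, z = np.meshgrid(g, g, g, indexing="ij")
    return x**2 + y**2 + z**2 <= r**2


def dilate_mask(mask: np.ndarray, radius_mm: float, grid: Grid3D) -> np.ndarray:
    """Morphological dilation with a spherical element of a physical radius."""
    if radius_mm < 0:
        raise ValueError("dilation radius must be non-negative")
    mask = np.asarray(mask, dtype=bool)
    radius_vox = int(round(radius_mm / grid.voxel_size))
    if radius_vox < 1 or not mask.any():
        return mask.copy()
    return ndimage.binary_dilation(mask, structure=_ball_structure(radius_vox))


def background_region(
    masks: OrganMasks, config: DetectConfig | None = None
) -> np.ndarray:
    """Body minus the dilated liver and lung masks."""
    if config is None:
        config = DetectConfig()
    for name in ("liver", "lungs"):
        if getattr(masks, name) is None:
            raise ValueError(f"{name} mask is required")
    r = config.dilation_radius
    return (
        masks.body
        & ~dilate_mask(masks.liver, r, masks.grid)
        & ~dilate_mask(masks.lungs, r, masks.grid)
    )


def _connectivity_structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])


def detect_depositions(
    recon: Reconstruction,
    masks: OrganMasks,
    injected_activity: float,
    config: DetectConfig | None = None,
) -> list[Deposition]:
    """Detect extrahepatic depositions in a reconstruction.

    Returns depositions sorted by activity, descending.  A reconstruction
    with zero total activity yields an empty list.
    """
    if config is None:
        config = DetectConfig()
    if injected_activity <= 0:
        raise ValueError("injected_activity must be positive")
    values = recon.volume.values
    total_recon = float(values.sum())
    if total_recon <= 0:
        return []
    bg = background_region(masks, config)
    conc_cutoff = config.concentration_threshold_frac * injected_activity  # MBq/ml
    candidate = bg & (recon.volume.concentration() > conc_cutoff)
    if not candidate.any():
        return []
    labels, n_labels = ndimage.label(
        candidate, structure=_connectivity_structure(config.connectivity)
    )
    activity_cutoff = config.cluster_activity_frac * total_recon
    cluster_act = ndimage.sum_labels(values, labels, index=np.arange(1, n_labels + 1))
    out: list[Deposition] = []
    for lab, act in zip(range(1, n_labels + 1), cluster_act):
        if act > activity_cutoff:
            mask = labels == lab
            com = ndimage.center_of_mass(values, labels, lab)
            out.append(Deposition(mask=mask, activity=float(act), centroid=tuple(com)))
    out.sort(key=lambda d: d.activity, reverse=True)
    return out
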