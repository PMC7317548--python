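"""Voxel grids and the volumes that live on them.

All physical geometry is expressed in millimetres so that the same phantom
description can be voxelised on grids of any resolution.  The world origin
sits at the centre of the grid; array index ``(i, j, k)`` maps to world
coordinate ``(idx - (n - 1)/2) * voxel_size`` on each axis.  Axis 2 (``k``)
is the scanner rotation axis (craniocaudal, z); axes 0 and 1 span the
transaxial plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Grid3D",
    "ActivityVolume",
    "AttenuationVolume",
    "OrganMasks",
]


@dataclass(frozen=True)
class Grid3D:
    """Isotropic voxel grid.

    Parameters
    ----------
    shape
        Number of voxels along each axis.
    voxel_size
        Isotropic voxel edge length in mm.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size: float = 3.9

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"shape must be three positive integers, got {self.shape}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size**3

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in millilitres (1 ml = 1000 mm^3)."""
        return self.voxel_volume_mm3 / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        n = self.shape[axis]
        return (np.arange(n) - (n - 1) / 2.0) * self.voxel_size

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-coordinate meshgrid (mm), ``indexing='ij'``."""
        return np.meshgrid(
            self.axis_coords(0), self.axis_coords(1), self.axis_coords(2), indexing="ij"
        )

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * self.voxel_size for n in self.shape)


def _check_on_grid(values: np.ndarray, grid: Grid3D, name: str) -> np.ndarray:
    values = np.asarray(values)
    if values.shape != grid.shape:
        raise ValueError(f"{name} shape {values.shape} does not match grid {grid.shape}")
    return values


@dataclass
class ActivityVolume:
    """Per-voxel activity in MBq on a :class:`Grid3D`."""

    grid: Grid3D
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = _check_on_grid(self.values, self.grid, "activity").astype(
            np.float64, copy=False
        )
        if np.any(self.values < 0):
            raise ValueError("activity values must be non-negative")

    def total(self) -> float:
        """Total activity in MBq."""
        return float(self.values.sum())

    def concentration(self) -> np.ndarray:
        """Per-voxel activity concentration in MBq/ml."""
        return self.values / self.grid.voxel_volume_ml


@dataclass
class AttenuationVolume:
    """Per-voxel linear attenuation coefficient at 140 keV, in mm^-1."""

    grid: Grid3D
    mu: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.mu = _check_on_grid(self.mu, self.grid, "mu").astype(np.float64, copy=False)
        if np.any(self.mu < 0):
            raise ValueError("attenuation coefficients must be non-negative")


@dataclass
class OrganMasks:
    """Boolean organ delineations on a common grid.

    Invariants: liver and lungs are disjoint, every organ lies inside the
    body, and deposition masks are disjoint from liver and lungs.
    """

    grid: Grid3D
    body: np.ndarray = field(repr=False)
    liver: np.ndarray = field(repr=False)
    lungs: np.ndarray = field(repr=False)
    depositions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        for name in ("body", "liver", "lungs", "depositions"):
            arr = _check_on_grid(getattr(self, name), self.grid, name)
            setattr(self, name, arr.astype(bool, copy=False))
        if np.any(self.liver & self.lungs):
            raise ValueError("liver and lung masks overlap")
        for name in ("liver", "lungs", "depositions"):
            if np.any(getattr(self, name) & ~self.body):
                raise ValueError(f"{name} mask extends outside the body")
        if np.any(self.depositions & (self.liver | self.lungs)):
            raise ValueError("deposition mask overlaps liver or lungs")
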