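"""Digital liver/lung phantom generation for Tc-99m-MAA scout imaging.

The phantom emulates a radioembolization pretreatment distribution: liver
and lungs uniformly filled with activity split by the lung shunt fraction
(LSF), plus one spherical extrahepatic deposition placed in the abdominal
background near the stomach.  Anatomy is a geometric surrogate — elliptical
body cylinder, two ellipsoidal lungs, one ellipsoidal liver — chosen so the
count statistics and organ adjacency of a torso scan are reproduced without
anatomical spline modelling.

All geometry parameters are in millimetres in world coordinates (origin at
the grid centre), so the same configuration voxelises consistently on grids
of any resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import ActivityVolume, AttenuationVolume, Grid3D, OrganMasks

__all__ = [
    "PhantomConfig",
    "OrganGeometry",
    "sphere_mask",
    "ellipsoid_mask",
    "make_phantom",
]

# Narrow-beam linear attenuation coefficients at 140 keV, mm^-1.
MU_SOFT_TISSUE = 0.0155
MU_LUNG = 0.004


@dataclass(frozen=True)
class OrganGeometry:
    """Centres and semi-axes (mm) of the surrogate anatomy.

    The liver ellipsoid volume (~1790 ml) is chosen so that, at the study's
    total activity of 150 MBq with LSF 5%, the liver concentration comes out
    at ~0.08 MBq/ml, matching the clinically representative configuration.
    """

    body_semi_axes: tuple[float, float] = (180.0, 120.0)
    body_half_height: float = 235.0
    liver_center: tuple[float, float, float] = (60.0, 25.0, 30.0)
    liver_semi_axes: tuple[float, float, float] = (95.0, 75.0, 60.0)
    lung_centers: tuple[tuple[float, float, float], ...] = (
        (-70.0, -20.0, 150.0),
        (70.0, -20.0, 150.0),
    )
    lung_semi_axes: tuple[float, float, float] = (55.0, 65.0, 80.0)
    dep_reference_center: tuple[float, float, float] = (-40.0, -80.0, -30.0)


@dataclass(frozen=True)
class PhantomConfig:
    """One study configuration: deposition properties plus global activity.

    Parameters
    ----------
    dep_concentration
        Extrahepatic deposition activity concentration, MBq/ml.
    dep_volume
        Deposition volume, ml.
    dep_shift
        Inferior (downward, -z) shift of the deposition from its reference
        location, in cm.
    lsf
        Lung shunt fraction: lung / (lung + liver) activity.
    total_activity
        Total phantom activity, MBq (deposition + liver + lungs).
    """

    dep_concentration: float = 0.10
    dep_volume: float = 15.19
    dep_shift: float = 0.0
    lsf: float = 0.05
    total_activity: float = 150.0
    geometry: OrganGeometry = field(default_factory=OrganGeometry)

    def __post_init__(self) -> None:
        if not (0.0 <= self.lsf < 1.0):
            raise ValueError(f"lsf must be in [0, 1), got {self.lsf}")
        if self.dep_volume < 0:
            raise ValueError("dep_volume must be non-negative")
        if self.dep_concentration < 0:
            raise ValueError("dep_concentration must be non-negative")
        if self.total_activity <= 0:
            raise ValueError("total_activity must be positive")

    @property
    def dep_activity(self) -> float:
        """Nominal deposition activity in MBq (concentration x volume)."""
        return self.dep_concentration * self.dep_volume

    @property
    def dep_center(self) -> tuple[float, float, float]:
        cx, cy, cz = self.geometry.dep_reference_center
        return (cx, cy, cz - 10.0 * self.dep_shift)


def sphere_mask(
    center: tuple[float, float, float], volume: float, grid: Grid3D
) -> np.ndarray:
    """Voxelise a sphere of the given volume (ml) centred at ``center`` (mm).

    The radius follows from ``V = 4/3 pi r^3``; a voxel is set when its
    centre lies within the radius.  Raises if any part of the analytic
    sphere extends beyond the grid.
    """
    if volume < 0:
        raise ValueError("volume must be non-negative")
    if volume == 0:
        return np.zeros(grid.shape, dtype=bool)
    radius = (3.0 * volume * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    half_extent = np.array(grid.extent_mm) / 2.0
    if np.any(np.abs(np.asarray(center)) + radius > half_extent):
        raise ValueError(
            f"sphere of radius {radius:.1f} mm at {center} extends outside the grid"
        )
    x, y, z = grid.meshgrid()
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    return d2 <= radius**2


def ellipsoid_mask(
    center: tuple[float, float, float],
    semi_axes: tuple[float, float, float],
    grid: Grid3D,
) -> np.ndarray:
    """Voxelise an axis-aligned ellipsoid (mm units)."""
    x, y, z = grid.meshgrid()
    q = (
        ((x - center[0]) / semi_axes[0]) ** 2
        + ((y - center[1]) / semi_axes[1]) ** 2
        + ((z - center[2]) / semi_axes[2]) ** 2
    )
    return q <= 1.0


def _body_mask(geom: OrganGeometry, grid: Grid3D) -> np.ndarray:
    x, y, z = grid.meshgrid()
    a, b = geom.body_semi_axes
    return ((x / a) ** 2 + (y / b) ** 2 <= 1.0) & (np.abs(z) <= geom.body_half_height)


def make_phantom(
    config: PhantomConfig, grid: Grid3D | None = None
) -> tuple[ActivityVolume, AttenuationVolume, OrganMasks]:
    """Build activity, attenuation and organ masks for one configuration.

    Activity assignment: the deposition receives exactly
    ``dep_concentration * dep_volume`` MBq spread uniformly over its
    voxelised sphere; the remainder of ``total_activity`` is split between
    lungs and liver as ``lsf : (1 - lsf)``, each uniform over its mask.
    Attenuation is soft tissue inside the body, lung tissue inside the
    lungs, zero outside the body.
    """
    if grid is None:
        grid = Grid3D()
    geom = config.geometry

    body = _body_mask(geom, grid)
    liver = ellipsoid_mask(geom.liver_center, geom.liver_semi_axes, grid) & body
    lungs = np.zeros(grid.shape, dtype=bool)
    for lc in geom.lung_centers:
        lungs |= ellipsoid_mask(lc, geom.lung_semi_axes, grid)
    lungs &= body
    lungs &= ~liver
    if not liver.any() or not lungs.any():
        raise ValueError("liver or lung mask is empty on this grid")

    dep = sphere_mask(config.dep_center, config.dep_volume, grid)
    if np.any(dep & (liver | lungs)):
        raise ValueError("deposition overlaps the liver or lung mask")
    if np.any(dep & ~body):
        raise ValueError("deposition extends outside the body")

    dep_activity = config.dep_activity if dep.any() else 0.0
    organ_activity = config.total_activity - dep_activity
    if organ_activity <= 0:
        raise ValueError("deposition activity exceeds total phantom activity")

    values = np.zeros(grid.shape, dtype=np.float64)
    if dep.any() and dep_activity > 0:
        values[dep] = dep_activity / dep.sum()
    values[lungs] = config.lsf * organ_activity / lungs.sum()
    values[liver] = (1.0 - config.lsf) * organ_activity / liver.sum()

    mu = np.zeros(grid.shape, dtype=np.float64)
    mu[body] = MU_SOFT_TISSUE
    mu[lungs] = MU_LUNG

    masks = OrganMasks(grid=grid, body=body, liver=liver, lungs=lungs, depositions=dep)
    return ActivityVolume(grid, values), AttenuationVolume(grid, mu), masks
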