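"""File I/O: NIfTI volumes, projection sets with JSON sidecars, YAML configs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .acquisition import Orbit, ProjectionSet
from .grids import Grid3D

__all__ = [
    "write_volume",
    "read_volume",
    "write_projections",
    "read_projections",
    "write_config_yaml",
    "read_config_yaml",
]


def _affine(grid: Grid3D) -> np.ndarray:
    """RAS affine with the world origin at the grid centre."""
    aff = np.diag([grid.voxel_size] * 3 + [1.0])
    aff[:3, 3] = -(np.array(grid.shape) - 1) / 2.0 * grid.voxel_size
    return aff


def write_volume(path: str | Path, values: np.ndarray, grid: Grid3D) -> None:
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), _affine(grid))
    img.header.set_zooms((grid.voxel_size,) * 3)
    nib.save(img, str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, Grid3D]:
    img = nib.load(str(path))
    # zooms are stored in float32; round off the representation error
    voxel = round(float(img.header.get_zooms()[0]), 6)
    data = np.asarray(img.dataobj)
    return data, Grid3D(tuple(data.shape), voxel)


def write_projections(path_stem: str | Path, projections: ProjectionSet) -> None:
    """Store a projection set as two NIfTI stacks plus a JSON sidecar.

    Integer counts round-trip bit exactly (stored as int32).
    """
    stem = Path(path_stem)
    for name, arr in (
        ("photopeak", projections.photopeak),
        ("scatter", projections.scatter_win),
    ):
        if np.issubdtype(np.asarray(arr).dtype, np.integer):
            data = np.asarray(arr, dtype=np.int32)
        else:
            data = np.asarray(arr, dtype=np.float32)
        nib.save(nib.Nifti1Image(data, np.eye(4)), str(stem) + f"_{name}.nii.gz")
    sidecar = {
        "angles_deg": projections.orbit.angles_deg.tolist(),
        "radii_mm": projections.orbit.radii_mm.tolist(),
        "duration_min": projections.duration,
        "photopeak_window_kev": [129.0, 150.0],
        "scatter_window_kev": [108.0, 129.0],
    }
    Path(str(stem) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_projections(path_stem: str | Path) -> ProjectionSet:
    stem = Path(path_stem)
    sidecar = json.loads(Path(str(stem) + ".json").read_text())
    pk = np.asarray(nib.load(str(stem) + "_photopeak.nii.gz").dataobj)
    sw = np.asarray(nib.load(str(stem) + "_scatter.nii.gz").dataobj)
    orbit = Orbit(
        angles_deg=np.array(sidecar["angles_deg"]),
        radii_mm=np.array(sidecar["radii_mm"]),
    )
    if pk.dtype.kind in "iu":
        pk = pk.astype(np.int64)
        sw = sw.astype(np.int64)
    return ProjectionSet(
        photopeak=pk, scatter_win=sw, orbit=orbit, duration=sidecar["duration_min"]
    )


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def write_config_yaml(path: str | Path, config) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))


def read_config_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
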