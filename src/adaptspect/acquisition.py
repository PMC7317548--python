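"""SPECT projection simulation.

Models a dual-head parallel-hole (LEHR) system as full angular coverage per
rotation: each 1-min rotation acquires all view angles over 360 degrees.
The projector is analytic and rotation-based — for every view the volume is
resampled into the detector frame with a sparse bilinear rotation operator,
depth-weighted by the cumulative attenuation towards the detector, summed
along the ray axis, and blurred with a distance-dependent Gaussian detector
response evaluated at the orbit radius.  Scatter in the photopeak window is
a surrogate: a fraction of the primary convolved with a wide Gaussian; the
lower scatter window is constructed as that term divided by the DEW factor
k, so dual-energy-window correction is exact in expectation.

The sparse rotation matrices make the projector's adjoint available exactly
(the matrix transpose), which keeps OSEM's forward and backward models
matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter

from .grids import ActivityVolume, AttenuationVolume, Grid3D

__all__ = [
    "Orbit",
    "AcquisitionConfig",
    "ProjectionSet",
    "body_tracing_orbit",
    "SystemModel",
    "forward_project",
    "sample_counts",
    "accumulate",
    "subsample_listmode",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass(frozen=True)
class Orbit:
    """Detector orbit: view angles (degrees) and per-angle radii (mm)."""

    angles_deg: np.ndarray
    radii_mm: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "angles_deg", np.asarray(self.angles_deg, dtype=float))
        object.__setattr__(self, "radii_mm", np.asarray(self.radii_mm, dtype=float))
        if self.angles_deg.shape != self.radii_mm.shape:
            raise ValueError("angles and radii must have the same length")

    @property
    def n_angles(self) -> int:
        return len(self.angles_deg)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Orbit):
            return NotImplemented
        return np.array_equal(self.angles_deg, other.angles_deg) and np.array_equal(
            self.radii_mm, other.radii_mm
        )


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition parameters.

    sensitivity is the expected photopeak count rate of the full system per
    unit activity (counts/s/MBq), so a 1-min scan of 150 MBq yields about
    sensitivity * 150 * 60 photopeak counts summed over all views.
    background_rate is the expected counts per projection bin per minute
    from an activity-free acquisition (room/electronic background), added to
    the photopeak window only.
    """

    n_angles: int = 120
    rotation_duration: float = 1.0  # minutes
    max_rotations: int = 20
    sensitivity: float = 180.0  # counts / s / MBq, full system
    psf_fwhm_intrinsic: float = 3.8  # mm
    psf_slope: float = 0.066  # FWHM growth per mm source-detector distance
    scatter_fraction: float = 0.3  # photopeak scatter-to-primary ratio
    scatter_fwhm: float = 60.0  # mm, width of the scatter spread surrogate
    scatter_window_k: float = 0.5  # DEW k for which the window pair is built
    background_rate: float = 8.0e-4  # counts / bin / minute
    gap_mm: float = 10.0  # patient-detector gap
    photopeak_window: tuple[float, float] = (129.0, 150.0)  # keV, label only
    scatter_window: tuple[float, float] = (108.0, 129.0)  # keV, label only

    def __post_init__(self) -> None:
        if self.max_rotations < 1:
            raise ValueError("max_rotations must be >= 1")
        for name in ("sensitivity", "scatter_fraction", "background_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def psf_fwhm_at(self, distance_mm: float) -> float:
        """Collimator-detector response FWHM (mm) at a source distance."""
        return float(
            np.hypot(self.psf_fwhm_intrinsic, self.psf_slope * distance_mm)
        )


@dataclass
class ProjectionSet:
    """Per-angle 2D count (or expected-count) arrays for both energy windows.

    Arrays are shaped ``(n_angles, nu, nv)`` with u the transaxial detector
    coordinate and v the axial one.  ``expected`` optionally retains the
    noise-free expectation a sampled set was drawn from.
    """

    photopeak: np.ndarray
    scatter_win: np.ndarray
    orbit: Orbit
    duration: float  # minutes
    expected: "ProjectionSet | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.photopeak = np.asarray(self.photopeak)
        self.scatter_win = np.asarray(self.scatter_win)
        if self.photopeak.shape != self.scatter_win.shape:
            raise ValueError("photopeak and scatter window shapes differ")
        if self.photopeak.shape[0] != self.orbit.n_angles:
            raise ValueError("projection angle count does not match orbit")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if np.any(self.photopeak < 0) or np.any(self.scatter_win < 0):
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.photopeak.shape

    def total_counts(self) -> float:
        return float(self.photopeak.sum())


def body_tracing_orbit(
    body_mask: np.ndarray,
    grid: Grid3D,
    gap_mm: float = 10.0,
    n_angles: int = 120,
) -> Orbit:
    """Non-circular orbit keeping a fixed gap from the body contour.

    For each view angle the detector radius is the maximal support of the
    body mask along the detector normal (plus half a voxel for the voxel
    extent) plus the gap.  Depends on the body mask only.
    """
    body_mask = np.asarray(body_mask, dtype=bool)
    if not body_mask.any():
        raise ValueError("body mask is empty")
    idx = np.argwhere(body_mask.any(axis=2))  # in-plane support
    x = (idx[:, 0] - (grid.shape[0] - 1) / 2.0) * grid.voxel_size
    y = (idx[:, 1] - (grid.shape[1] - 1) / 2.0) * grid.voxel_size
    angles = np.arange(n_angles) * (360.0 / n_angles)
    rad = np.deg2rad(angles)
    # support of the voxel-centre cloud along each detector normal
    proj = np.cos(rad)[:, None] * x[None, :] + np.sin(rad)[:, None] * y[None, :]
    radii = proj.max(axis=1) + grid.voxel_size / 2.0 + gap_mm
    return Orbit(angles_deg=angles, radii_mm=radii)


def _rotation_operator(n: int, angle_deg: float) -> sp.csr_matrix:
    """Sparse bilinear operator rotating a flattened (n, n) image in-plane.

    Output pixel (i, j) samples the input at the inverse-rotated position
    about the image centre; samples outside the grid contribute zero.
    """
    c = (n - 1) / 2.0
    th = np.deg2rad(angle_deg)
    ct, st = np.cos(th), np.sin(th)
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    xo = ii.ravel() - c
    yo = jj.ravel() - c
    # inverse rotation of the output coordinate
    xs = ct * xo + st * yo + c
    ys = -st * xo + ct * yo + c
    x0 = np.floor(xs).astype(np.int64)
    y0 = np.floor(ys).astype(np.int64)
    fx = xs - x0
    fy = ys - y0
    rows, cols, data = [], [], []
    out_idx = np.arange(n * n)
    for dx, wx in ((0, 1.0 - fx), (1, fx)):
        for dy, wy in ((0, 1.0 - fy), (1, fy)):
            xi = x0 + dx
            yi = y0 + dy
            w = wx * wy
            ok = (xi >= 0) & (xi < n) & (yi >= 0) & (yi < n) & (w > 0)
            rows.append(out_idx[ok])
            cols.append(xi[ok] * n + yi[ok])
            data.append(w[ok])
    mat = sp.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n * n, n * n),
        dtype=np.float32,
    )
    return mat.tocsr()


class SystemModel:
    """Matched forward/backward projection operator for one geometry.

    Precomputes, per view angle: the sparse in-plane rotation into the
    detector frame (rays along +axis 0 towards the detector), its exact
    transpose for backprojection, the attenuation weights in the detector
    frame, and the detector-response blur width at the orbit radius.
    Instances are reused across reconstructions of the same phantom.
    """

    def __init__(
        self,
        mu: AttenuationVolume,
        orbit: Orbit,
        config: AcquisitionConfig,
    ) -> None:
        grid = mu.grid
        nx, ny, nz = grid.shape
        if nx != ny:
            raise ValueError("transaxial grid must be square for the rotation operator")
        self.grid = grid
        self.orbit = orbit
        self.config = config
        self._n = nx
        self._nz = nz
        dv = grid.voxel_size
        self._rot: list[sp.csr_matrix] = []
        self._rot_t: list[sp.csr_matrix] = []
        self._att: list[np.ndarray] = []
        self._psf_sigma_pix: list[float] = []
        self._sens_cache: dict[int, list[np.ndarray]] = {}
        mu_flat = mu.mu.reshape(nx * ny, nz).astype(np.float32)
        for angle, radius in zip(orbit.angles_deg, orbit.radii_mm):
            # rotate by -angle so the detector normal moves onto the +x axis.
            # The forward rotation is the mass-conserving adjoint (splat) of
            # bilinear interpolation by +angle: total activity is preserved
            # exactly for any source, and the backprojector is then plain
            # bilinear interpolation — still an exact transpose pair.
            interp = _rotation_operator(nx, angle)
            self._rot.append(interp.T.tocsr())
            self._rot_t.append(interp)
            mu_rot = (self._rot[-1] @ mu_flat).reshape(nx, ny, nz)
            # cumulative attenuation from each voxel towards the detector
            # (+axis 0 side), counting half the voxel's own path
            csum = np.cumsum(mu_rot[::-1], axis=0)[::-1]
            self._att.append(np.exp(-dv * (csum - 0.5 * mu_rot)).astype(np.float32))
            sigma_mm = config.psf_fwhm_at(radius) * FWHM_TO_SIGMA
            self._psf_sigma_pix.append(sigma_mm / dv)

    @property
    def n_angles(self) -> int:
        return self.orbit.n_angles

    def count_factor(self, duration_min: float) -> float:
        """Counts per MBq of (attenuated) projected activity, per view."""
        return self.config.sensitivity * duration_min * 60.0 / self.n_angles

    def _blur(self, proj: np.ndarray, a: int) -> np.ndarray:
        s = self._psf_sigma_pix[a]
        if s <= 0:
            return proj
        return gaussian_filter(proj, s, mode="constant")

    def project_view(self, volume: np.ndarray, a: int) -> np.ndarray:
        """Attenuated, blurred parallel projection for one view (no count scale)."""
        n, nz = self._n, self._nz
        rot = (self._rot[a] @ volume.reshape(n * n, nz)).reshape(n, n, nz)
        return self._blur((rot * self._att[a]).sum(axis=0), a)

    def backproject_view(self, proj: np.ndarray, a: int) -> np.ndarray:
        """Exact adjoint of :meth:`project_view`."""
        n, nz = self._n, self._nz
        sm = self._blur(proj, a)
        vol = self._att[a] * sm[None, :, :]
        return (self._rot_t[a] @ vol.reshape(n * n, nz)).reshape(n, n, nz)

    def subset_sensitivity(self, n_subsets: int) -> list[np.ndarray]:
        """Per-subset backprojections of unit projections (unscaled A^T 1).

        Round-robin subsets (angle i -> subset i mod n_subsets).  Cached:
        the images depend only on the geometry, not on duration or data.
        """
        if n_subsets not in self._sens_cache:
            ones = np.ones((self._n, self._nz), dtype=np.float32)
            sens = []
            for s in range(n_subsets):
                img = np.zeros((self._n, self._n, self._nz), dtype=np.float32)
                for a in range(s, self.n_angles, n_subsets):
                    img += self.backproject_view(ones, a)
                sens.append(np.maximum(img, 0.0))
            self._sens_cache[n_subsets] = sens
        return self._sens_cache[n_subsets]

    def project(self, volume: np.ndarray, angles: np.ndarray | None = None) -> np.ndarray:
        """Stack of per-view projections, shape (n_views, nu, nv)."""
        volume = np.ascontiguousarray(volume, dtype=np.float32)
        if angles is None:
            angles = np.arange(self.n_angles)
        return np.stack([self.project_view(volume, a) for a in angles])

    def backproject(
        self, projs: np.ndarray, angles: np.ndarray | None = None
    ) -> np.ndarray:
        if angles is None:
            angles = np.arange(self.n_angles)
        out = np.zeros((self._n, self._n, self._nz), dtype=np.float32)
        for p, a in zip(projs, angles):
            out += self.backproject_view(np.ascontiguousarray(p, dtype=np.float32), a)
        return out


def forward_project(
    activity: ActivityVolume,
    mu: AttenuationVolume,
    orbit: Orbit,
    config: AcquisitionConfig,
    duration: float,
    model: SystemModel | None = None,
) -> ProjectionSet:
    """Noise-free expected-count projections for both energy windows.

    Photopeak expectation = primary (attenuated blurred line integrals,
    scaled to counts) + scatter surrogate + background; the scatter-window
    expectation is the scatter term divided by the DEW k so that
    ``k * scatter_win`` matches the photopeak scatter term exactly.
    """
    if model is None:
        model = SystemModel(mu, orbit, config)
    if activity.grid != mu.grid:
        raise ValueError("activity and attenuation grids differ")
    c = model.count_factor(duration)
    primary = model.project(activity.values) * c
    if config.scatter_fraction > 0:
        sigma_pix = config.scatter_fwhm * FWHM_TO_SIGMA / activity.grid.voxel_size
        scatter = config.scatter_fraction * gaussian_filter(
            primary, (0, sigma_pix, sigma_pix), mode="constant"
        )
    else:
        scatter = np.zeros_like(primary)
    photopeak = primary + scatter + config.background_rate * duration
    scatter_win = scatter / config.scatter_window_k
    return ProjectionSet(
        photopeak=photopeak.astype(np.float64),
        scatter_win=scatter_win.astype(np.float64),
        orbit=orbit,
        duration=duration,
    )


def sample_counts(expected: ProjectionSet, seed: int) -> ProjectionSet:
    """Draw independent Poisson counts per bin per window; deterministic in seed."""
    for arr in (expected.photopeak, expected.scatter_win):
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("expectations must be finite and non-negative")
    rng = np.random.default_rng(seed)
    return ProjectionSet(
        photopeak=rng.poisson(expected.photopeak).astype(np.int64),
        scatter_win=rng.poisson(expected.scatter_win).astype(np.int64),
        orbit=expected.orbit,
        duration=expected.duration,
        expected=expected,
    )


def accumulate(rotations: list[ProjectionSet]) -> ProjectionSet:
    """Bin-wise sum of rotations; durations add."""
    if not rotations:
        raise ValueError("cannot accumulate an empty list of rotations")
    first = rotations[0]
    for r in rotations[1:]:
        if r.shape != first.shape or r.orbit != first.orbit:
            raise ValueError("mismatched projection geometry in accumulate")
    expected = None
    if all(r.expected is not None for r in rotations):
        expected = accumulate([r.expected for r in rotations])
    return ProjectionSet(
        photopeak=sum(r.photopeak for r in rotations),
        scatter_win=sum(r.scatter_win for r in rotations),
        orbit=first.orbit,
        duration=sum(r.duration for r in rotations),
        expected=expected,
    )


def subsample_listmode(
    full: ProjectionSet, n_parts: int = 20, seed: int = 0
) -> list[ProjectionSet]:
    """Split a projection set into equal-duration parts event by event.

    Every count is treated as an individual list-mode event and assigned to
    one of ``n_parts`` equally probable parts (equivalent to shuffling the
    event list and cutting it into equal blocks).  The parts sum back to the
    input exactly, bin by bin.
    """
    if n_parts < 1:
        raise ValueError("n_parts must be >= 1")
    pk = np.asarray(full.photopeak)
    sw = np.asarray(full.scatter_win)
    if not (np.issubdtype(pk.dtype, np.integer) and np.issubdtype(sw.dtype, np.integer)):
        raise ValueError("list-mode subsampling requires integer counts")
    if n_parts == 1:
        return [
            ProjectionSet(
                photopeak=pk.copy(),
                scatter_win=sw.copy(),
                orbit=full.orbit,
                duration=full.duration,
            )
        ]
    rng = np.random.default_rng(seed)
    pvals = np.full(n_parts, 1.0 / n_parts)
    pk_split = rng.multinomial(pk.ravel(), pvals).reshape(pk.shape + (n_parts,))
    sw_split = rng.multinomial(sw.ravel(), pvals).reshape(sw.shape + (n_parts,))
    part_duration = full.duration / n_parts
    return [
        ProjectionSet(
            photopeak=pk_split[..., p],
            scatter_win=sw_split[..., p],
            orbit=full.orbit,
            duration=part_duration,
        )
        for p in range(n_parts)
    ]
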