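"""Projection simulation: orbit, projector physics, noise, subsampling."""

import numpy as np
import pytest

from adaptspect import (
    AcquisitionConfig,
    ActivityVolume,
    AttenuationVolume,
    Grid3D,
    Orbit,
    ProjectionSet,
    accumulate,
    body_tracing_orbit,
    forward_project,
    sample_counts,
    subsample_listmode,
)


def _point_source_setup(n=64, voxel=7.8, value=2.0, idx=(40, 28, 32), n_angles=16):
    grid = Grid3D((n, n, n), voxel)
    act = np.zeros(grid.shape)
    act[idx] = value
    mu = AttenuationVolume(grid, np.zeros(grid.shape))
    orbit = Orbit(np.arange(n_angles) * 360.0 / n_angles, np.full(n_angles, 200.0))
    cfg = AcquisitionConfig(n_angles=n_angles, scatter_fraction=0.0, background_rate=0.0)
    return ActivityVolume(grid, act), mu, orbit, cfg


class TestOrbit:
    def test_cylinder_body_gives_constant_radius(self):
        grid = Grid3D((64, 64, 64), 7.8)
        x, y, _ = grid.meshgrid()
        R = 120.0
        body = x**2 + y**2 <= R**2
        orbit = body_tracing_orbit(body, grid, gap_mm=10.0, n_angles=32)
        assert np.all(np.abs(orbit.radii_mm - (R + 10.0)) < grid.voxel_size)

    def test_single_voxel_body_radius_is_half_voxel(self):
        grid = Grid3D((33, 33, 33), 4.0)
        body = np.zeros(grid.shape, dtype=bool)
        body[16, 16, 16] = True  # isocentre voxel on the odd grid
        orbit = body_tracing_orbit(body, grid, gap_mm=0.0, n_angles=8)
        assert np.allclose(orbit.radii_mm, grid.voxel_size / 2.0)

    def test_orbit_is_pure_function_of_body(self, reference_phantom, half_grid):
        _, _, masks = reference_phantom
        o1 = body_tracing_orbit(masks.body, half_grid, 10.0, 32)
        o2 = body_tracing_orbit(masks.body, half_grid, 10.0, 32)
        assert o1 == o2

    def test_empty_body_raises(self, half_grid):
        with pytest.raises(ValueError, match="empty"):
            body_tracing_orbit(np.zeros(half_grid.shape, bool), half_grid)


class TestForwardProject:
    def test_zero_activity_zero_background_is_all_zero(self):
        act, mu, orbit, cfg = _point_source_setup(value=0.0)
        act = ActivityVolume(act.grid, np.zeros(act.grid.shape))
        ps = forward_project(act, mu, orbit, cfg, 1.0)
        assert ps.photopeak.max() == 0.0
        assert ps.scatter_win.max() == 0.0

    def test_count_conservation_point_source_no_attenuation(self):
        # total expectation over all views = sensitivity * A * duration
        act, mu, orbit, cfg = _point_source_setup()
        ps = forward_project(act, mu, orbit, cfg, 1.0)
        expected_total = cfg.sensitivity * 2.0 * 60.0
        assert ps.total_counts() == pytest.approx(expected_total, rel=0.01)

    def test_beer_lambert_through_100mm_slab(self):
        # path of 100 mm of soft tissue attenuates by e^-1.55 = 0.212
        grid = Grid3D((81, 81, 81), 2.5)
        mu_arr = np.zeros(grid.shape)
        mu_arr[41:81, :, :] = 0.0155  # 40 voxels x 2.5 mm towards the detector
        src = np.zeros(grid.shape)
        src[30, 40, 40] = 1.0
        orbit = Orbit(np.array([0.0]), np.array([150.0]))
        cfg = AcquisitionConfig(
            n_angles=1,
            scatter_fraction=0.0,
            background_rate=0.0,
            psf_fwhm_intrinsic=0.0,
            psf_slope=0.0,
        )
        attenuated = forward_project(
            ActivityVolume(grid, src), AttenuationVolume(grid, mu_arr), orbit, cfg, 1.0
        ).total_counts()
        free = forward_project(
            ActivityVolume(grid, src),
            AttenuationVolume(grid, np.zeros(grid.shape)),
            orbit,
            cfg,
            1.0,
        ).total_counts()
        assert attenuated / free == pytest.approx(np.exp(-1.55), rel=0.01)

    def test_projector_linearity_in_activity(self):
        act, mu, orbit, cfg = _point_source_setup()
        cfg_bg0 = cfg
        p1 = forward_project(act, mu, orbit, cfg_bg0, 1.0)
        act3 = ActivityVolume(act.grid, 3.0 * act.values)
        p3 = forward_project(act3, mu, orbit, cfg_bg0, 1.0)
        assert np.allclose(p3.photopeak, 3.0 * p1.photopeak, rtol=1e-5, atol=1e-9)

    def test_expectation_scales_with_duration(self, noiseless_projection, reference_phantom, reference_model, small_acq):
        activity, mu, _ = reference_phantom
        orbit, model = reference_model
        p20 = forward_project(activity, mu, orbit, small_acq, 20.0, model=model)
        assert np.allclose(p20.photopeak, 20.0 * noiseless_projection.photopeak, rtol=1e-5)

    def test_dew_window_construction(self, noiseless_projection, small_acq):
        # scatter window expectation is exactly scatter/k, so k * scatter_win
        # reproduces the photopeak scatter term (here via total sums)
        ps = noiseless_projection
        primary_plus = ps.photopeak - small_acq.scatter_window_k * ps.scatter_win
        # what remains is primary + background, strictly positive
        assert primary_plus.min() >= 0
        assert ps.scatter_win.sum() > 0

    def test_grid_mismatch_raises(self):
        act, mu, orbit, cfg = _point_source_setup()
        other = Grid3D((32, 32, 32), 7.8)
        mu_bad = AttenuationVolume(other, np.zeros(other.shape))
        with pytest.raises(ValueError):
            forward_project(act, mu_bad, orbit, cfg, 1.0)


class TestSampleCounts:
    def test_poisson_moments(self):
        grid = Grid3D((4, 160, 160), 1.0)  # ~10^5 bins via projection shape
        orbit = Orbit(np.array([0.0]), np.array([100.0]))
        lam = np.full((1, 160, 160), 100.0)
        ps = ProjectionSet(lam, np.zeros_like(lam), orbit, 1.0)
        counts = sample_counts(ps, seed=7)
        mean = counts.photopeak.mean()
        var = counts.photopeak.var()
        assert mean == pytest.approx(100.0, rel=0.01)
        assert var / mean == pytest.approx(1.0, abs=0.05)

    def test_deterministic_given_seed(self, noiseless_projection):
        a = sample_counts(noiseless_projection, seed=42)
        b = sample_counts(noiseless_projection, seed=42)
        assert np.array_equal(a.photopeak, b.photopeak)
        assert np.array_equal(a.scatter_win, b.scatter_win)
        c = sample_counts(noiseless_projection, seed=43)
        assert not np.array_equal(a.photopeak, c.photopeak)

    def test_zero_expectation_gives_zero_counts(self):
        orbit = Orbit(np.array([0.0]), np.array([100.0]))
        zeros = np.zeros((1, 8, 8))
        counts = sample_counts(ProjectionSet(zeros, zeros, orbit, 1.0), seed=0)
        assert counts.photopeak.max() == 0

    def test_negative_expectation_rejected(self):
        orbit = Orbit(np.array([0.0]), np.array([100.0]))
        bad = np.full((1, 4, 4), -1.0)
        ps = ProjectionSet.__new__(ProjectionSet)  # bypass validation
        ps.photopeak = bad
        ps.scatter_win = np.zeros_like(bad)
        ps.orbit = orbit
        ps.duration = 1.0
        ps.expected = None
        with pytest.raises(ValueError):
            sample_counts(ps, seed=0)


class TestAccumulate:
    def test_five_rotations_sum(self, noiseless_projection):
        rots = [sample_counts(noiseless_projection, seed=s) for s in range(5)]
        acc = accumulate(rots)
        assert acc.duration == pytest.approx(5.0)
        assert np.array_equal(acc.photopeak, sum(r.photopeak for r in rots))

    def test_associativity(self, noiseless_projection):
        a, b, c = (sample_counts(noiseless_projection, seed=s) for s in range(3))
        left = accumulate([accumulate([a, b]), c])
        flat = accumulate([a, b, c])
        assert np.array_equal(left.photopeak, flat.photopeak)
        assert left.duration == pytest.approx(flat.duration)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            accumulate([])

    def test_mismatched_geometry_raises(self, noiseless_projection):
        other_orbit = Orbit(
            noiseless_projection.orbit.angles_deg,
            noiseless_projection.orbit.radii_mm + 5.0,
        )
        other = ProjectionSet(
            noiseless_projection.photopeak,
            noiseless_projection.scatter_win,
            other_orbit,
            1.0,
        )
        with pytest.raises(ValueError):
            accumulate([sample_counts(noiseless_projection, 0), other])


class TestSubsampleListmode:
    def test_partition_is_exact(self, noiseless_projection):
        full = sample_counts(noiseless_projection, seed=3)
        parts = subsample_listmode(full, n_parts=20, seed=1)
        assert len(parts) == 20
        assert np.array_equal(sum(p.photopeak for p in parts), full.photopeak)
        assert np.array_equal(sum(p.scatter_win for p in parts), full.scatter_win)
        for p in parts:
            assert p.duration == pytest.approx(full.duration / 20)

    def test_single_part_is_identity(self, noiseless_projection):
        full = sample_counts(noiseless_projection, seed=3)
        (only,) = subsample_listmode(full, n_parts=1, seed=0)
        assert np.array_equal(only.photopeak, full.photopeak)

    def test_parts_have_equal_expected_share(self):
        # 10^6 events split 20 ways: each part within 2% of total/20
        orbit = Orbit(np.array([0.0]), np.array([100.0]))
        counts = np.full((1, 100, 100), 100, dtype=np.int64)  # 10^6 events
        full = ProjectionSet(counts, np.zeros_like(counts), orbit, 20.0)
        parts = subsample_listmode(full, n_parts=20, seed=5)
        sizes = np.array([p.photopeak.sum() for p in parts])
        assert np.all(np.abs(sizes - 50_000) < 0.02 * 50_000)

    def test_float_counts_rejected(self, noiseless_projection):
        with pytest.raises(ValueError, match="integer"):
            subsample_listmode(noiseless_projection, n_parts=4, seed=0)

    def test_invalid_part_count_rejected(self, noiseless_projection):
        full = sample_counts(noiseless_projection, seed=0)
        with pytest.raises(ValueError):
            subsample_listmode(full, n_parts=0, seed=0)
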