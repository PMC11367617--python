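import numpy as np
import pytest

from tfusnav import (TransducerPose, TransducerSpec, bowl_source_plane,
                     build_beam_grid, intensity_from_pressure, propagate,
                     resample_to_grid, solve_beam)
from tfusnav.solver import BeamGrid, LocalFields

from conftest import SMALL
from rs_oracle import rayleigh_sommerfeld

Z_AXIS = np.array([0.0, 0.0, 1.0])


def axial_pose(axis=Z_AXIS, position=(0, 0, 0)):
    return TransducerPose(0, np.asarray(position, float), np.asarray(axis, float))


def water_grid(nu, nz, spacing=0.4615):
    """Hand-built axis-aligned grid for controlled propagation tests."""
    origin = np.array([-(nu - 1) / 2.0 * spacing, -(nu - 1) / 2.0 * spacing, 0.0])
    return BeamGrid(origin=origin, u=np.array([1.0, 0, 0]),
                    v=np.array([0, 1.0, 0]), w=Z_AXIS,
                    spacing=spacing, shape=(nu, nu, nz))


class TestBeamGrid:
    def test_lambda_over_five_spacing(self):
        grid = build_beam_grid(axial_pose(), TransducerSpec())
        assert grid.spacing == pytest.approx(1500.0 / 650e3 * 1e3 / 5)
        assert round(grid.spacing, 2) == 0.46

    def test_reduced_domain_extents(self):
        spec = TransducerSpec(aperture_diameter=61.0, focal_distance=80.0)
        grid = build_beam_grid(axial_pose(), spec)
        nu, nv, nz = grid.shape
        h = grid.spacing
        assert (nu - 1) * h == pytest.approx(1.3 * 61, abs=h)
        assert (nz - 1) * h == pytest.approx(2 * 80, abs=h)

    def test_axes_orthonormal_right_handed(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            axis = rng.standard_normal(3)
            grid = build_beam_grid(axial_pose(axis), TransducerSpec())
            R = np.stack([grid.u, grid.v, grid.w], axis=1)
            np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-12)
            assert np.linalg.det(R) == pytest.approx(1.0)
            np.testing.assert_allclose(grid.w,
                                       axis / np.linalg.norm(axis), atol=1e-12)

    def test_exit_plane_centered_on_pose(self):
        pose = axial_pose(position=(5.0, -3.0, 2.0))
        grid = build_beam_grid(pose, TransducerSpec())
        nu, nv, _ = grid.shape
        center = (grid.origin + grid.spacing
                  * ((nu - 1) / 2 * grid.u + (nv - 1) / 2 * grid.v))
        np.testing.assert_allclose(center, pose.position, atol=1e-9)


class TestSource:
    def test_center_amplitude_and_phase(self):
        spec = TransducerSpec()
        x, y = water_grid(175, 2).transverse_mm()
        p = bowl_source_plane(spec, x, y)
        ic = 87
        assert p[ic, ic] == pytest.approx(1.0)

    def test_zero_outside_aperture(self):
        spec = TransducerSpec(aperture_diameter=30.0)
        x, y = water_grid(175, 2).transverse_mm()
        p = bowl_source_plane(spec, x, y)
        r = np.sqrt(x ** 2 + y ** 2)
        assert np.all(p[r > 15.0 + 1e-6] == 0)
        np.testing.assert_allclose(np.abs(p[r < 15.0 - 1e-6]), 1.0, atol=1e-12)

    def test_radial_symmetry(self):
        x, y = water_grid(175, 2).transverse_mm()
        p = bowl_source_plane(TransducerSpec(), x, y)
        np.testing.assert_allclose(p, p[::-1, :], atol=1e-12)
        np.testing.assert_allclose(p, p.T, atol=1e-12)

    def test_grid_narrower_than_aperture_rejected(self):
        x, y = water_grid(21, 2).transverse_mm()
        with pytest.raises(ValueError, match="aperture"):
            bowl_source_plane(TransducerSpec(aperture_diameter=61.0), x, y)


class TestResample:
    def test_constant_volume_gives_constant_fields(self, sphere_head):
        pose = axial_pose(position=(0, 0, -40.0))
        grid = build_beam_grid(pose, SMALL)
        import copy
        head = copy.copy(sphere_head)
        head.rho = np.full(sphere_head.shape, 1200.0)
        head.c = np.full(sphere_head.shape, 1600.0)
        head.alpha = np.full(sphere_head.shape, 3.0)
        f = resample_to_grid(head, grid)
        inside = np.abs(grid.world_coords()).max(axis=-1) < 40.0
        np.testing.assert_allclose(f.rho[inside], 1200.0, rtol=1e-6)
        np.testing.assert_allclose(f.c[inside], 1600.0, rtol=1e-6)

    def test_grid_outside_head_is_water(self, sphere_head):
        pose = axial_pose(position=(500.0, 500.0, 500.0))
        f = resample_to_grid(sphere_head, build_beam_grid(pose, SMALL))
        assert np.all(f.rho == 1000.0) and np.all(f.c == 1500.0)
        assert np.all(f.alpha == 0.0)

    def test_trilinear_spot_check(self, sphere_head):
        pose = axial_pose(position=(0, 0, -60.0))
        grid = build_beam_grid(pose, SMALL)
        f = resample_to_grid(sphere_head, grid)
        pt = (40, 41, 88)
        world = (grid.origin + grid.spacing
                 * (pt[0] * grid.u + pt[1] * grid.v + pt[2] * grid.w))
        # independent corner-weighted sum on the head voxel grid
        inv = np.linalg.inv(sphere_head.affine)
        vox = inv[:3, :3] @ world + inv[:3, 3]
        i0 = np.floor(vox).astype(int)
        fr = vox - i0
        expected = 0.0
        vol = np.asarray(sphere_head.c, np.float32)
        for di in (0, 1):
            for dj in (0, 1):
                for dk in (0, 1):
                    w = ((fr[0] if di else 1 - fr[0])
                         * (fr[1] if dj else 1 - fr[1])
                         * (fr[2] if dk else 1 - fr[2]))
                    expected += w * vol[i0[0] + di, i0[1] + dj, i0[2] + dk]
        assert f.c[pt] == pytest.approx(expected, rel=1e-5)


class TestPropagateAnalyticLimits:
    def test_zero_distance_identity(self):
        grid = water_grid(64, 1)
        rng = np.random.default_rng(0)
        src = rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
        out = propagate(src, LocalFields.water(grid.shape), grid, 650e3)
        np.testing.assert_array_equal(out.pressure[:, :, 0],
                                      src.astype(np.complex64))

    def test_homogeneous_attenuation_law(self):
        grid = water_grid(16, 120)
        fields = LocalFields.water(grid.shape)
        fields.alpha[:] = 5.0  # Np/m/MHz -> 3.25 Np/m at 650 kHz
        src = np.ones((16, 16), complex)
        out = propagate(src, fields, grid, 650e3, taper_width=0)
        z_m = grid.z_mm() * 1e-3
        amp = np.abs(out.pressure[8, 8, :]).astype(float)
        np.testing.assert_allclose(amp, np.exp(-5.0 * 0.65 * z_m), rtol=1e-3)

    def test_linearity_in_source(self):
        grid = water_grid(48, 30)
        fields = LocalFields.water(grid.shape)
        rng = np.random.default_rng(1)
        src = rng.standard_normal((48, 48)) + 1j * rng.standard_normal((48, 48))
        a = 2.7 - 1.3j
        p1 = propagate(src, fields, grid, 650e3).pressure
        p2 = propagate((a * src), fields, grid, 650e3).pressure
        np.testing.assert_allclose(p2, a * p1, rtol=2e-4, atol=2e-4)

    def test_flat_bone_slab_transmission(self):
        # normal-incidence plane wave through a 6 mm slab of cortical bone
        # in water; one-way amplitude is T12*T21 = 4 Z1 Z2 / (Z1+Z2)^2
        grid = water_grid(8, 100)
        fields = LocalFields.water(grid.shape)
        z = grid.z_mm()
        slab = (z >= 20.0) & (z < 26.0)
        fields.c[:, :, slab] = 3514.0
        fields.rho[:, :, slab] = 1908.0
        src = np.ones((8, 8), complex)
        out = propagate(src, fields, grid, 650e3, taper_width=0)
        Z1, Z2 = 1000.0 * 1500.0, 1908.0 * 3514.0
        expected = 4 * Z1 * Z2 / (Z1 + Z2) ** 2
        amp_after = np.abs(out.pressure[4, 4, -1])
        assert amp_after == pytest.approx(expected, rel=0.05)

    def test_power_conserved_before_focus(self):
        beam = solve_beam(axial_pose(), SMALL, None, keep_pressure=True)
        grid = beam.grid
        m = 12  # exclude absorbing strip + margin
        interior = np.s_[m:-m, m:-m]
        z = grid.z_mm()
        pre = (z > 2.0) & (z < SMALL.focal_distance - 5.0)
        power = [np.sum(np.abs(beam.pressure[interior + (k,)]) ** 2)
                 for k in np.flatnonzero(pre)]
        p0 = np.sum(np.abs(beam.pressure[interior + (0,)]) ** 2)
        assert np.allclose(power, p0, rtol=0.01)

    def test_time_reversal_refocuses(self):
        # reciprocity sanity: in lossless homogeneous water, conjugating
        # the field at a downstream plane and marching it the same
        # distance recovers the conjugate of the upstream field (up to
        # evanescent content, which has decayed by the upstream plane)
        grid = water_grid(96, 61)
        fields = LocalFields.water(grid.shape)
        x, y = grid.transverse_mm()
        src = bowl_source_plane(TransducerSpec(aperture_diameter=12.0,
                                               focal_distance=20.0), x, y)
        p = propagate(src, fields, grid, 650e3, taper_width=0).pressure
        k0, k1 = 20, 60
        back_grid = water_grid(96, k1 - k0 + 1)
        q = propagate(np.conj(p[:, :, k1]),
                      LocalFields.water(back_grid.shape),
                      back_grid, 650e3, taper_width=0).pressure
        target = np.conj(p[:, :, k0])
        scale = np.abs(target).max()
        np.testing.assert_allclose(q[:, :, -1], target, atol=2e-3 * scale)

    def test_step_size_guard(self):
        grid = water_grid(16, 4, spacing=2.0)  # > lambda/2 = 1.15 mm
        with pytest.raises(ValueError, match="lambda/2"):
            propagate(np.ones((16, 16)), LocalFields.water(grid.shape),
                      grid, 650e3)

    def test_nan_fields_rejected(self):
        grid = water_grid(16, 4)
        fields = LocalFields.water(grid.shape)
        fields.c[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            propagate(np.ones((16, 16)), fields, grid, 650e3)


class TestAgainstRayleighSommerfeld:
    """The brute-force diffraction integral is the independent oracle."""

    def test_focus_position_and_focal_plane_profile(self):
        beam = solve_beam(axial_pose(), SMALL, None, keep_pressure=True)
        grid = beam.grid
        nu = grid.shape[0]
        lam = SMALL.wavelength_mm()
        x, y = grid.transverse_mm()
        src = bowl_source_plane(SMALL, x, y)

        # this low-Fresnel-number bowl has a real diffraction focal shift,
        # so the reference for the peak position is the oracle itself
        onax = np.abs(beam.pressure[nu // 2, nu // 2, :])
        z_peak = grid.z_mm()[int(np.argmax(onax))]
        zs = np.arange(25.0, 50.0, 0.25)
        obs = np.column_stack([np.zeros_like(zs), np.zeros_like(zs), zs])
        rs = np.abs(rayleigh_sommerfeld(src, grid.spacing, SMALL.frequency, obs))
        assert abs(zs[int(np.argmax(rs))] - z_peak) <= lam
        assert z_peak < SMALL.focal_distance  # shift is toward the source

        # focal-plane |p| cross-correlation on a decimated grid
        dec = np.arange(0, nu, 3)
        gx = (dec - (nu - 1) / 2) * grid.spacing
        OX, OY = np.meshgrid(gx, gx, indexing="ij")
        obs = np.column_stack([OX.ravel(), OY.ravel(),
                               np.full(OX.size, SMALL.focal_distance)])
        rs_f = np.abs(rayleigh_sommerfeld(src, grid.spacing, SMALL.frequency,
                                          obs))
        kz = int(round(SMALL.focal_distance / grid.spacing))
        sol = np.abs(beam.pressure[np.ix_(dec, dec)][:, :, kz]).ravel()
        ncc = (rs_f @ sol) / np.sqrt((rs_f @ rs_f) * (sol @ sol))
        assert ncc >= 0.99


class TestIntensity:
    def test_direct_formula(self):
        f = LocalFields(rho=np.full((1, 1, 1), 1000.0),
                        c=np.full((1, 1, 1), 1500.0),
                        alpha=np.zeros((1, 1, 1)))
        p = np.ones((1, 1, 1), complex)
        I = intensity_from_pressure(p, f)
        assert I[0, 0, 0] == pytest.approx(1.0 / 3e6)
        assert intensity_from_pressure(0 * p, f)[0, 0, 0] == 0.0
        np.testing.assert_allclose(intensity_from_pressure(3 * p, f), 9 * I,
                                   rtol=1e-6)
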