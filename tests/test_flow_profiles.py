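import numpy as np
import pytest

from paddlepress import flow_profiles as fp
from paddlepress.errors import InvalidOffsetError, UnreliableProfileError
from paddlepress.fields import GridGeometry, ScalarField, VelocityFieldSequence
from paddlepress.kinematics import resample_centerline
from paddlepress.synthetic import make_uniform_flow


def vertical_centerline(n=21, length=1.0, x=0.0):
    pts = np.column_stack([np.full(n, x), np.linspace(0, length, n)])
    return resample_centerline(pts, n)


def make_profile(fractions, lee, flo, lee_p=None, flo_p=None):
    return fp.SideProfile(
        fractions=np.asarray(fractions, dtype=float),
        leeward_speed=np.asarray(lee, dtype=float),
        flowward_speed=np.asarray(flo, dtype=float),
        offset=0.1,
        leeward_pressure=None if lee_p is None else np.asarray(lee_p, dtype=float),
        flowward_pressure=None if flo_p is None else np.asarray(flo_p, dtype=float),
    )


class TestOffsetCurves:
    def test_vertical_centerline_motion_plus_x(self):
        cl = vertical_centerline()
        lee, flo = fp.offset_curves(cl, 0.1, np.array([1.0, 0.0]))
        assert np.allclose(flo[:, 0], 0.1)
        assert np.allclose(lee[:, 0], -0.1)

    def test_zero_offset_is_centerline(self):
        cl = vertical_centerline()
        lee, flo = fp.offset_curves(cl, 0.0, np.array([1.0, 0.0]))
        assert np.allclose(lee, cl.points) and np.allclose(flo, cl.points)

    def test_reversed_motion_swaps_sides(self):
        cl = vertical_centerline()
        lee1, flo1 = fp.offset_curves(cl, 0.1, np.array([1.0, 0.0]))
        lee2, flo2 = fp.offset_curves(cl, 0.1, np.array([-1.0, 0.0]))
        assert np.allclose(lee1, flo2) and np.allclose(flo1, lee2)

    def test_excessive_offset_rejected(self):
        # hairpin centerline: a large offset cannot be embedded
        t = np.linspace(0, np.pi, 41)
        pts = np.column_stack([0.2 * np.cos(t), 0.2 * np.sin(t)])
        cl = resample_centerline(pts, 41)
        with pytest.raises(InvalidOffsetError):
            fp.offset_curves(cl, 0.3, np.array([0.0, 1.0]))


class TestSampleProfile:
    def test_uniform_flow_constant_speed(self):
        sc = make_uniform_flow(0.02, grid_shape=(32, 32), spacing=0.01)
        cl = vertical_centerline(21, 0.2, x=0.15)
        cl.points[:, 1] += 0.05
        curves = fp.offset_curves(cl, 0.02, np.array([1.0, 0.0]))
        prof = fp.sample_profile(sc.fields, 1, curves, cl)
        assert np.allclose(prof.leeward_speed, 0.02)
        assert np.allclose(prof.flowward_speed, 0.02)
        assert fp.side_velocity_ratio(prof) == pytest.approx(1.0)

    def test_quiescent_field_flags_undefined_peak(self):
        sc = make_uniform_flow(0.0, grid_shape=(32, 32), spacing=0.01)
        cl = vertical_centerline(21, 0.2, x=0.15)
        cl.points[:, 1] += 0.05
        curves = fp.offset_curves(cl, 0.02, np.array([1.0, 0.0]))
        prof = fp.sample_profile(sc.fields, 1, curves, cl)
        assert np.isnan(fp.peak_flow_fraction(prof))
        assert np.isnan(fp.side_velocity_ratio(prof))

    def test_speed_peak_at_vortex_location(self):
        # a line vortex placed beside the centerline at 0.7 L: the leeward
        # profile peaks at that arc fraction
        from paddlepress.synthetic import make_line_vortex

        L, delta = 0.2, 0.02
        # perpendicular distance from the leeward curve exceeds the radius
        # of peak azimuthal speed (1.12 rc), so the along-curve speed peaks
        # at closest approach
        sc = make_line_vortex(
            circulation=1e-3, core_radius=0.02, center=(0.15 - delta - 0.045, 0.05 + 0.7 * L),
            grid_shape=(64, 64), spacing=0.005,
        )
        cl = vertical_centerline(41, L, x=0.15)
        cl.points[:, 1] += 0.05
        cl = resample_centerline(cl.points, 41)
        curves = fp.offset_curves(cl, delta, np.array([1.0, 0.0]))  # leeward at -x
        prof = fp.sample_profile(sc.fields, 1, curves, cl)
        spacing = cl.fractions[1] - cl.fractions[0]
        peak_lee = cl.fractions[int(np.argmax(prof.leeward_speed))]
        assert peak_lee == pytest.approx(0.7, abs=spacing + 1e-9)
        assert fp.side_velocity_ratio(prof) > 1.0

    def test_too_many_undefined_samples_rejected(self):
        sc = make_uniform_flow(0.01, grid_shape=(16, 16), spacing=0.01)
        cl = vertical_centerline(21, 0.4, x=0.075)  # extends beyond the grid
        curves = fp.offset_curves(cl, 0.01, np.array([1.0, 0.0]))
        with pytest.raises(UnreliableProfileError):
            fp.sample_profile(sc.fields, 1, curves, cl)


class TestMetrics:
    def test_peak_constructed_at_068(self):
        frac = np.linspace(0, 1, 101)
        speed = np.exp(-((frac - 0.68) ** 2) / 0.01)
        prof = make_profile(frac, speed, 0.5 * speed)
        assert fp.peak_flow_fraction(prof) == pytest.approx(0.68)

    def test_peak_monotone_profile_is_tip(self):
        frac = np.linspace(0, 1, 51)
        prof = make_profile(frac, frac, 0.5 * frac)
        assert fp.peak_flow_fraction(prof) == 1.0

    def test_peak_tie_breaks_to_smaller_fraction(self):
        frac = np.array([0.2, 0.4, 0.6, 0.8])
        speed = np.array([0.1, 1.0, 1.0, 0.1])
        prof = make_profile(frac, speed, speed * 0.5)
        assert fp.peak_flow_fraction(prof) == 0.4

    def test_velocity_ratio_constructed_131(self):
        frac = np.linspace(0, 1, 21)
        flo = np.full(21, 0.02)
        prof = make_profile(frac, 1.31 * flo, flo)
        assert fp.side_velocity_ratio(prof) == pytest.approx(1.31)

    def test_pressure_ratio_sign_filtered(self):
        frac = np.linspace(0, 1, 10)
        prof = make_profile(
            frac, np.ones(10), np.ones(10),
            lee_p=np.full(10, -5.0), flo_p=np.full(10, 1.0),
        )
        assert fp.pressure_asymmetry_ratio(prof) == pytest.approx(5.0)

    def test_pressure_ratio_antisymmetric_unity(self):
        frac = np.linspace(0, 1, 10)
        p = np.linspace(0.5, 2.0, 10)
        prof = make_profile(frac, np.ones(10), np.ones(10), lee_p=-p, flo_p=p)
        assert fp.pressure_asymmetry_ratio(prof) == pytest.approx(1.0)

    def test_pressure_ratio_undefined_without_positive_flowward(self):
        frac = np.linspace(0, 1, 10)
        prof = make_profile(
            frac, np.ones(10), np.ones(10),
            lee_p=np.full(10, -5.0), flo_p=np.full(10, -1.0),
        )
        assert np.isnan(fp.pressure_asymmetry_ratio(prof))


class TestSceneMetrics:
    def test_mirrored_field_reciprocal_ratio(self):
        # speed field asymmetric in x about the centerline at x = c
        n, spacing = 33, 0.01
        grid = GridGeometry(nx=n, ny=n, dx=spacing, dy=spacing)
        X, Y = grid.mesh()
        c = 0.16
        u = 0.01 + 0.05 * (X - c)
        seq = VelocityFieldSequence(
            u=np.repeat(u[None], 3, 0), v=np.zeros((3, n, n)), grid=grid, dt=1.0
        )
        u_m = u[:, ::-1]  # mirror about the centerline column
        seq_m = VelocityFieldSequence(
            u=np.repeat(u_m[None], 3, 0), v=np.zeros((3, n, n)), grid=grid, dt=1.0
        )
        cl = vertical_centerline(21, 0.2, x=c)
        cl.points[:, 1] += 0.06
        cl = resample_centerline(cl.points, 21)
        curves = fp.offset_curves(cl, 0.02, np.array([1.0, 0.0]))
        r1 = fp.side_velocity_ratio(fp.sample_profile(seq, 1, curves, cl))
        r2 = fp.side_velocity_ratio(fp.sample_profile(seq_m, 1, curves, cl))
        assert r1 == pytest.approx(1.0 / r2, rel=1e-9)

    def test_rotation_invariance_of_metrics(self):
        # rotate the whole scene by 90 degrees: metrics unchanged
        n, spacing = 33, 0.01
        grid = GridGeometry(nx=n, ny=n, dx=spacing, dy=spacing)
        X, Y = grid.mesh()
        rng = np.random.default_rng(3)
        cx = cy = (n - 1) * spacing / 2
        u0 = 0.01 + 0.03 * np.sin(20 * (X - cx)) * np.cos(15 * (Y - cy))
        v0 = 0.02 * np.cos(25 * (X - cx))
        seq = VelocityFieldSequence(
            u=np.repeat(u0[None], 3, 0), v=np.repeat(v0[None], 3, 0), grid=grid, dt=1.0
        )
        # rotation by +90 deg about the grid center maps node (j, i) ->
        # (i, n-1-j); vector components transform (u, v) -> (-v, u)
        u_r = np.zeros_like(u0)
        v_r = np.zeros_like(v0)
        for j in range(n):
            for i in range(n):
                u_r[i, n - 1 - j] = -v0[j, i]
                v_r[i, n - 1 - j] = u0[j, i]
        seq_r = VelocityFieldSequence(
            u=np.repeat(u_r[None], 3, 0), v=np.repeat(v_r[None], 3, 0), grid=grid, dt=1.0
        )
        cl = vertical_centerline(21, 0.16, x=cx + 0.03)
        cl.points[:, 1] += 0.08
        cl = resample_centerline(cl.points, 21)
        rot = np.array([[0.0, -1.0], [1.0, 0.0]])
        center = np.array([cx, cy])
        cl_r = resample_centerline((cl.points - center) @ rot.T + center, 21)
        motion = np.array([1.0, 0.0])
        curves = fp.offset_curves(cl, 0.02, motion)
        curves_r = fp.offset_curves(cl_r, 0.02, rot @ motion)
        p1 = fp.sample_profile(seq, 1, curves, cl)
        p2 = fp.sample_profile(seq_r, 1, curves_r, cl_r)
        assert fp.side_velocity_ratio(p1) == pytest.approx(
            fp.side_velocity_ratio(p2), rel=0.01
        )
        assert fp.peak_flow_fraction(p1) == pytest.approx(
            fp.peak_flow_fraction(p2), abs=0.06
        )

    def test_paddle_scene_ratios_exceed_unity(self, paddle_scene, fluid):
        from paddlepress.pressure import compute_pressure_sequence
        from paddlepress.synthetic import paddle_motion_direction

        sc = paddle_scene
        fields, _ = compute_pressure_sequence(
            sc.fields, masks=[m.raster for m in sc.masks], fluid=fluid
        )
        t = sc.fields.n_frames // 2
        cl = sc.centerlines[t]
        delta = 4 * sc.fields.grid.dx
        curves = fp.offset_curves(cl, delta, paddle_motion_direction(sc, t))
        prof = fp.sample_profile(sc.fields, t, curves, cl, pressure=fields[t])
        assert fp.side_velocity_ratio(prof) > 1.0
        assert fp.pressure_asymmetry_ratio(prof) > 1.0
        assert 0.3 < fp.peak_flow_fraction(prof) < 0.9
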