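import numpy as np
import pytest

from paddlepress import surface_forces as sf
from paddlepress.errors import (
    AlignmentError,
    InvalidAxisError,
    InvalidContourError,
    UnreliableSamplingError,
)
from paddlepress.fields import GridGeometry, ScalarField
from paddlepress.synthetic import ellipse_contour


def circle_surface(n=256, r=1.0):
    return sf.make_surface(ellipse_contour((0, 0), r, r, 720), n, closed=True)


def linear_field(a=2.0, extent=2.0, n=101):
    grid = GridGeometry(nx=n, ny=n, dx=2 * extent / (n - 1), dy=2 * extent / (n - 1),
                        x0=-extent, y0=-extent)
    X, _ = grid.mesh()
    return ScalarField(values=a * X, grid=grid, units="Pa")


class TestMakeSurface:
    def test_circle_segments_and_normals(self):
        surf = circle_surface(360)
        assert surf.ds == pytest.approx(2 * np.pi / 360, rel=1e-3)
        radial = surf.midpoints / np.linalg.norm(surf.midpoints, axis=1)[:, None]
        ang = np.arccos(np.clip(np.einsum("ij,ij->i", radial, surf.normals), -1, 1))
        assert ang.max() < 1e-3

    def test_closed_surface_normal_sum_vanishes(self):
        square = np.array([[0.0, 0.0], [2.0, 0.0], [2.0, 2.0], [0.0, 2.0]])
        surf = sf.make_surface(square, 64, closed=True)
        total = (surf.normals * surf.ds).sum(axis=0)
        assert np.linalg.norm(total) < 1e-6 * surf.perimeter

    def test_reversed_order_same_outward_normals(self):
        pts = ellipse_contour((0, 0), 2.0, 1.0, 100)
        a = sf.make_surface(pts, 64, closed=True)
        b = sf.make_surface(pts[::-1], 64, closed=True)
        # outward orientation is auto-fixed: mean normal radial alignment equal
        def radial_score(s):
            rad = s.midpoints / np.linalg.norm(s.midpoints, axis=1)[:, None]
            return np.einsum("ij,ij->i", rad, s.normals).mean()
        assert radial_score(a) == pytest.approx(radial_score(b), abs=1e-3)
        for s in (a, b):  # every normal points away from the interior
            rad = s.midpoints / np.linalg.norm(s.midpoints, axis=1)[:, None]
            assert np.einsum("ij,ij->i", rad, s.normals).min() > 0

    def test_self_intersecting_rejected(self):
        bow = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(InvalidContourError):
            sf.make_surface(bow, 16, closed=True)

    def test_open_surface_needs_orientation_point(self):
        line = np.array([[0.0, 0.0], [0.0, 1.0]])
        with pytest.raises(InvalidContourError):
            sf.make_surface(line, 8, closed=False)
        surf = sf.make_surface(line, 8, closed=False, leeward_point=(-1.0, 0.5))
        assert np.allclose(surf.normals[:, 0], 1.0)  # away from leeward point


class TestSampling:
    def test_constant_field(self):
        grid = GridGeometry(nx=41, ny=41, dx=0.1, dy=0.1, x0=-2, y0=-2)
        field = ScalarField(values=np.full((41, 41), 7.5), grid=grid, units="Pa")
        surf = circle_surface(64)
        p, flagged = sf.sample_surface_pressure(field, surf, probe_offset_cells=0)
        assert np.allclose(p, 7.5)
        assert not flagged.any()

    def test_linear_field_exact_and_offset_shift(self):
        a = 2.0
        field = linear_field(a)
        surf = circle_surface(64)
        p0, _ = sf.sample_surface_pressure(field, surf, probe_offset_cells=0)
        assert np.allclose(p0, a * surf.midpoints[:, 0], atol=1e-12)
        p2, _ = sf.sample_surface_pressure(field, surf, probe_offset_cells=2)
        shift = 2 * min(field.grid.dx, field.grid.dy) * a * surf.normals[:, 0]
        assert np.allclose(p2 - p0, shift, atol=1e-12)

    def test_undefined_probes_use_nearest_then_fail(self):
        grid = GridGeometry(nx=41, ny=41, dx=0.1, dy=0.1, x0=-2, y0=-2)
        vals = np.full((41, 41), 3.0)
        defined = np.ones_like(vals, dtype=bool)
        defined[:, :15] = False  # region x < -0.5 undefined
        vals[~defined] = np.nan
        field = ScalarField(values=vals, grid=grid, units="Pa", defined=defined)
        surf = circle_surface(64)
        p, flagged = sf.sample_surface_pressure(field, surf, probe_offset_cells=0)
        assert flagged.any() and np.allclose(p, 3.0)
        defined[:, :] = False
        vals[:] = np.nan
        field = ScalarField(values=vals, grid=grid, units="Pa", defined=defined)
        with pytest.raises(UnreliableSamplingError):
            sf.sample_surface_pressure(field, surf, probe_offset_cells=0)


class TestForceTorque:
    def test_constant_pressure_closed_surface(self):
        surf = circle_surface(256)
        p = np.full(surf.n_segments, 11.0)
        F = sf.integrate_surface_force(p, surf)
        assert np.linalg.norm(F) < 1e-6 * 11.0 * surf.perimeter
        tau = sf.integrate_surface_torque(p, surf, pivot=(0.3, -0.2))
        assert abs(tau) < 1e-6 * 11.0 * surf.perimeter

    def test_linear_field_divergence_theorem(self):
        a, r = 2.0, 1.0
        surf = circle_surface(256, r)
        p = a * surf.midpoints[:, 0]
        F = sf.integrate_surface_force(p, surf)
        assert F[0] == pytest.approx(-a * np.pi * r**2, rel=0.005)
        assert abs(F[1]) < 1e-10

    def test_force_linearity(self):
        surf = circle_surface(64)
        p = surf.midpoints[:, 0] ** 2 + 0.5
        assert np.allclose(
            sf.integrate_surface_force(2 * p, surf),
            2 * sf.integrate_surface_force(p, surf),
        )

    def test_torque_examples(self):
        a = 3.0
        surf = circle_surface(512)
        # p = a x about the center: force is central, zero torque
        tau = sf.integrate_surface_torque(a * surf.midpoints[:, 0], surf, (0.0, 0.0))
        assert abs(tau) < 1e-6
        # p = a y, pivot at (1, 0): tau = a pi (divergence-theorem force
        # (0, -a pi) applied at the centroid, crossed with the -pivot offset)
        tau = sf.integrate_surface_torque(a * surf.midpoints[:, 1], surf, (1.0, 0.0))
        assert tau == pytest.approx(a * np.pi, rel=0.005)

    def test_random_smooth_field_divergence_oracle(self):
        rng = np.random.default_rng(5)
        surf = circle_surface(256, 1.0)
        # p = alpha x + beta y + gamma x y: grad integrates analytically
        # over the unit disk: integral of grad p = (alpha, beta) * pi
        alpha, beta, gamma = rng.normal(size=3)
        x, y = surf.midpoints[:, 0], surf.midpoints[:, 1]
        p = alpha * x + beta * y + gamma * x * y
        F = sf.integrate_surface_force(p, surf)
        assert np.allclose(F, (-alpha * np.pi, -beta * np.pi), atol=0.01 * max(1, abs(alpha), abs(beta)))

    def test_segment_count_convergence(self):
        a = 1.0
        errs = []
        for n in (16, 32, 64, 128):
            surf = circle_surface(n)
            F = sf.integrate_surface_force(a * surf.midpoints[:, 0], surf)
            errs.append(abs(F[0] + a * np.pi))
        assert all(e2 < e1 for e1, e2 in zip(errs, errs[1:]))


class TestPullPush:
    def test_two_segment_toy(self):
        # leeward segment at p = -1 with outward normal along the swimming
        # direction, flowward segment at p = +1 with normal opposed: both
        # contribute +1 N/m of forward thrust
        surf = sf.SurfaceContour(
            midpoints=np.array([[0.0, 1.0], [0.0, -1.0]]),
            normals=np.array([[0.0, 1.0], [0.0, -1.0]]),
            ds=1.0,
            closed=False,
            vertices=np.zeros((3, 2)),
        )
        pull, push, total = sf.pull_push_decompose(
            np.array([-1.0, 1.0]), surf, np.array([0.0, 1.0])
        )
        assert (pull, push, total) == (1.0, 1.0, 2.0)

    def test_all_negative_pressures(self):
        surf = circle_surface(64)
        p = -np.abs(surf.midpoints[:, 0]) - 0.1
        pull, push, total = sf.pull_push_decompose(p, surf, np.array([0.0, 1.0]))
        assert push == 0.0 and total == pull

    def test_axis_flip_negates(self):
        surf = circle_surface(64)
        p = surf.midpoints[:, 0]
        up = sf.pull_push_decompose(p, surf, np.array([0.0, 1.0]))
        down = sf.pull_push_decompose(p, surf, np.array([0.0, -1.0]))
        assert np.allclose(up, [-x for x in down])

    def test_non_unit_axis_rejected(self):
        surf = circle_surface(64)
        with pytest.raises(InvalidAxisError):
            sf.pull_push_decompose(np.zeros(64), surf, np.array([0.0, 1.1]))

    def test_identity_total_eq_pull_plus_push(self):
        rng = np.random.default_rng(0)
        surf = circle_surface(128)
        for _ in range(20):
            p = rng.normal(size=128)
            pull, push, total = sf.pull_push_decompose(p, surf, np.array([1.0, 0.0]))
            assert total == pull + push  # exact partition


class TestStrokeSeries:
    def test_constant_fields(self):
        grid = GridGeometry(nx=41, ny=41, dx=0.1, dy=0.1, x0=-2, y0=-2)
        X, _ = grid.mesh()
        field = ScalarField(values=0.5 * X, grid=grid, units="Pa")
        surf = circle_surface(64, 0.8)
        series = sf.stroke_series([field] * 4, [surf] * 4, np.array([1.0, 0.0]),
                                  probe_offset_cells=0)
        assert np.allclose(series.pull, series.pull[0])
        single = sf.stroke_series([field], [surf], np.array([1.0, 0.0]),
                                  probe_offset_cells=0)
        assert series.pull_push_ratio == pytest.approx(single.pull_push_ratio)

    def test_window_of_one_frame(self):
        grid = GridGeometry(nx=21, ny=21, dx=0.2, dy=0.2, x0=-2, y0=-2)
        X, _ = grid.mesh()
        field = ScalarField(values=X, grid=grid, units="Pa")
        surf = circle_surface(64, 0.8)
        series = sf.stroke_series([field] * 3, [surf] * 3, np.array([1.0, 0.0]),
                                  window=(1, 1), probe_offset_cells=0)
        assert len(series.pull) == 1

    def test_misaligned_sequences_rejected(self):
        grid = GridGeometry(nx=21, ny=21, dx=0.2, dy=0.2, x0=-2, y0=-2)
        field = ScalarField(values=np.zeros((21, 21)), grid=grid, units="Pa")
        surf = circle_surface(64, 0.8)
        with pytest.raises(AlignmentError):
            sf.stroke_series([field] * 3, [surf] * 2, np.array([1.0, 0.0]))
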