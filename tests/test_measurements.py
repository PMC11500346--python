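"""Height, ellipse-approximated circumferences, and mesh volume."""

import numpy as np
import pytest

from meshcomp import autodiff as ad
from meshcomp.bodymodel import PoseShape, forward, shaped_vertices_t
from meshcomp.measurements import (
    Anthropometry,
    EllipseParams,
    circumference_t,
    ellipse_perimeter,
    ellipse_perimeter_quadrature,
    fit_ellipse,
    height_t,
    measure_circumference,
    measure_height,
    measure_volume,
    project_ring,
)


def ellipse_points(a, b, n, angle=0.0, center=(0.0, 0.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    p = np.stack([a * np.cos(t), b * np.sin(t)], axis=1)
    R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    return p @ R.T + np.asarray(center)


class TestEllipseFit:
    def test_circle_recovered(self):
        e = fit_ellipse(ellipse_points(0.4, 0.4, 12))
        assert abs(e.semi_major - 0.4) < 1e-8
        assert abs(e.semi_minor - 0.4) < 1e-8

    def test_axis_aligned_ellipse_exact(self):
        e = fit_ellipse(ellipse_points(0.15, 0.10, 16))
        assert abs(e.semi_major - 0.15) < 1e-8
        assert abs(e.semi_minor - 0.10) < 1e-8

    def test_rotated_noisy_ellipse_monte_carlo(self, rng):
        """Semi-axes recovered within 5e-3 under sigma=1e-3 noise."""
        for _ in range(10):
            pts = ellipse_points(0.15, 0.10, 24, angle=np.pi / 6, center=(0.3, -0.2))
            pts = pts + rng.normal(0, 1e-3, pts.shape)
            e = fit_ellipse(pts)
            assert abs(e.semi_major - 0.15) < 5e-3
            assert abs(e.semi_minor - 0.10) < 5e-3

    def test_degenerate_configurations_rejected(self):
        line = np.stack([np.linspace(0, 1, 8), np.linspace(0, 2, 8)], axis=1)
        with pytest.raises(ValueError):
            fit_ellipse(line)
        with pytest.raises(ValueError):
            fit_ellipse(np.zeros((6, 2)))
        with pytest.raises(ValueError):
            fit_ellipse(ellipse_points(0.1, 0.1, 4))

    def test_fit_differentiable_wrt_points(self, rng):
        pts = ellipse_points(0.15, 0.10, 16, angle=0.4)
        t = ad.tensor(pts.copy(), requires_grad=True)
        from meshcomp.measurements import ellipse_perimeter_t, fit_ellipse_t

        out = fit_ellipse_t(t)
        ellipse_perimeter_t(out["semi_major"], out["semi_minor"]).backward()
        i, k = 3, 0
        eps = 1e-7

        def peri(p):
            o = fit_ellipse_t(ad.tensor(p))
            return float(ellipse_perimeter_t(o["semi_major"], o["semi_minor"]).item())

        pp, pm = pts.copy(), pts.copy()
        pp[i, k] += eps
        pm[i, k] -= eps
        fd = (peri(pp) - peri(pm)) / (2 * eps)
        assert abs(t.grad[i, k] - fd) < 1e-4 * max(abs(fd), 1e-6)


class TestPerimeter:
    def test_circle_closed_form(self):
        e = EllipseParams(np.zeros(2), 0.4, 0.4, 0.0)
        assert abs(ellipse_perimeter(e) - 2 * np.pi * 0.4) < 1e-12

    @pytest.mark.parametrize("a", [0.05, 0.2, 1.3])
    def test_equal_axes_give_2_pi_a(self, a):
        assert abs(ellipse_perimeter(EllipseParams(np.zeros(2), a, a, 0.0)) - 2 * np.pi * a) < 1e-12

    def test_oracle_equivalence_100_random_ellipses(self, rng):
        """Ramanujan II vs Gauss-Legendre arc-length quadrature, aspect <= 4."""
        worst = 0.0
        for _ in range(100):
            a = rng.uniform(0.05, 0.5)
            b = a / rng.uniform(1.0, 4.0)
            approx = ellipse_perimeter(EllipseParams(np.zeros(2), a, b, 0.0))
            exact = ellipse_perimeter_quadrature(a, b)
            worst = max(worst, abs(approx - exact) / exact)
        assert worst < 1e-5


class TestProjectRing:
    def test_planar_ring_is_isometric(self, rng):
        pts2 = rng.normal(size=(8, 2))
        pts3 = np.insert(pts2, 1, 0.7, axis=1)  # constant body-axis coordinate
        proj = project_ring(pts3, np.arange(8))
        d3 = np.linalg.norm(pts3[:, [0, 2]][None] - pts3[:, [0, 2]][:, None], axis=-1)
        d2 = np.linalg.norm(proj[None] - proj[:, None], axis=-1)
        np.testing.assert_allclose(d2, d3, atol=1e-12)

    def test_helical_ring_projects_to_circle(self):
        t = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        r = 0.14
        helix = np.stack([r * np.cos(t), np.linspace(0, 0.2, 16), r * np.sin(t)], axis=1)
        proj = project_ring(helix, np.arange(16))
        np.testing.assert_allclose(np.linalg.norm(proj, axis=1), r, atol=1e-12)

    def test_short_ring_rejected(self):
        with pytest.raises(ValueError):
            project_ring(np.zeros((4, 3)), np.arange(4))


class TestCircumference:
    def test_cylinder_fixture_within_half_percent(self):
        """Helical ring on a radius-0.14 cylinder -> 2*pi*r within 0.5%."""
        t = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        r = 0.14
        verts = np.stack([r * np.cos(t), 0.9 + 0.01 * np.sin(3 * t), r * np.sin(t)], axis=1)
        proj = project_ring(verts, np.arange(24))
        e = fit_ellipse(proj)
        circ = ellipse_perimeter(e)
        assert abs(circ - 2 * np.pi * r) / (2 * np.pi * r) < 0.005

    def test_homogeneity_degree_one(self, model):
        v = model.template_vertices
        c1 = measure_circumference(model, v, "waist")
        c2 = measure_circumference(model, v * 1.1, "waist")
        assert abs(c2 / c1 - 1.1) < 1e-6

    def test_hip_wider_than_waist(self, model):
        v = model.template_vertices
        assert measure_circumference(model, v, "hip") > measure_circumference(model, v, "waist")

    def test_unknown_ring_name(self, model):
        with pytest.raises(KeyError):
            measure_circumference(model, model.template_vertices, "thumb")

    def test_rigid_invariance(self, model, rng):
        v = model.template_vertices
        c0 = measure_circumference(model, v, "waist")
        # translation and rotation about the body axis preserve circumferences
        shift = v + rng.normal(size=3)
        ang = 0.7
        R = np.array(
            [[np.cos(ang), 0, -np.sin(ang)], [0, 1, 0], [np.sin(ang), 0, np.cos(ang)]]
        )
        rot = v @ R.T
        assert abs(measure_circumference(model, shift, "waist") / c0 - 1) < 1e-6
        assert abs(measure_circumference(model, rot, "waist") / c0 - 1) < 1e-6

    def test_end_to_end_gradient_wrt_shape(self, model, rng):
        beta0 = rng.normal(size=model.n_shape) * 0.3
        bt = ad.tensor(beta0.copy(), requires_grad=True)
        circumference_t(model, shaped_vertices_t(model, bt), "waist").backward()

        def f(b):
            return float(
                circumference_t(model, shaped_vertices_t(model, ad.tensor(b)), "waist").item()
            )

        eps = 1e-6
        for i in range(model.n_shape):
            bp, bm = beta0.copy(), beta0.copy()
            bp[i] += eps
            bm[i] -= eps
            fd = (f(bp) - f(bm)) / (2 * eps)
            assert abs(bt.grad[i] - fd) <= 1e-3 * max(abs(fd), 1e-4)


class TestHeight:
    def test_fixture_extent(self, model):
        v = model.template_vertices
        top, heel = model.extrema_ids
        expected = v[top, 1] - v[heel, 1]
        assert abs(measure_height(model, np.zeros(model.n_shape)) - expected) < 1e-12

    def test_monotone_in_stature(self, model):
        b = np.zeros(model.n_shape)
        h0 = measure_height(model, b)
        b[0] = 1.0
        h1 = measure_height(model, b)
        b[0] = 2.0
        assert measure_height(model, b) > h1 > h0

    def test_gradient_matches_finite_differences(self, model, rng):
        beta0 = rng.normal(size=model.n_shape) * 0.5
        bt = ad.tensor(beta0.copy(), requires_grad=True)
        height_t(model, bt).backward()
        eps = 1e-6
        for i in range(model.n_shape):
            bp, bm = beta0.copy(), beta0.copy()
            bp[i] += eps
            bm[i] -= eps
            fd = (measure_height(model, bp) - measure_height(model, bm)) / (2 * eps)
            assert abs(bt.grad[i] - fd) <= 1e-4 * max(abs(fd), 1e-6)


class TestVolume:
    def _cube(self, side=1.0):
        import trimesh

        box = trimesh.creation.box(extents=(side, side, side))
        return np.asarray(box.vertices), np.asarray(box.faces)

    def test_unit_cube_is_1000_liters(self):
        v, f = self._cube()
        assert abs(measure_volume((v, f)) - 1000.0) < 1e-9

    def test_sphere_within_one_percent(self):
        import trimesh

        s = trimesh.creation.icosphere(subdivisions=3, radius=0.2)
        vol = measure_volume((np.asarray(s.vertices), np.asarray(s.faces)))
        exact = 4.0 / 3.0 * np.pi * 0.2**3 * 1000.0
        assert abs(vol - exact) / exact < 0.01

    def test_mirrored_mesh_same_volume(self, model):
        v = model.template_vertices
        mirrored = v * np.array([-1.0, 1.0, 1.0])
        assert abs(
            measure_volume((mirrored, model.faces)) - measure_volume((v, model.faces))
        ) < 1e-9

    def test_matches_trimesh_oracle(self, model):
        import trimesh

        tm = trimesh.Trimesh(model.template_vertices, model.faces, process=False)
        assert abs(measure_volume((model.template_vertices, model.faces)) - abs(tm.volume) * 1000) < 1e-6

    def test_open_mesh_warns(self):
        v, f = self._cube()
        with pytest.warns(UserWarning, match="watertight"):
            measure_volume((v, f[:-2]))


class TestAnthropometryType:
    def test_validation(self):
        with pytest.raises(ValueError):
            Anthropometry(height=-1.7, waist_circ=0.8, hip_circ=0.9, weight=70, sex="female")
        with pytest.raises(ValueError):
            Anthropometry(height=1.7, waist_circ=0.8, hip_circ=0.9, weight=70, sex="other")

    def test_bmi_and_sex_code(self):
        a = Anthropometry(height=1.70, waist_circ=0.8, hip_circ=0.9, weight=77.6, sex="male")
        assert abs(a.bmi - 77.6 / 1.70**2) < 1e-9
        assert a.sex_code == 1.0
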