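"""Geometry, joint-surface fitting and the three-step bone morphing."""

import numpy as np
import pytest

from kneemech import geometry as G
from kneemech.fixtures import generate_morph_pair
from kneemech.kinematics import axis_angle


@pytest.fixture
def rng():
    return np.random.default_rng(42)


class TestAffine:
    def test_identity_on_tetrahedron(self):
        tet = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        aff = G.fit_affine(tet, tet)
        assert np.allclose(aff.linear, np.eye(3), atol=1e-12)
        assert np.allclose(aff.translation, 0, atol=1e-12)

    def test_generate_and_recover(self, rng):
        S = rng.standard_normal((36, 3))
        A = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
        t = rng.standard_normal(3)
        aff = G.fit_affine(S, S @ A.T + t)
        assert np.abs(aff.linear - A).max() < 1e-10
        assert np.abs(aff.translation - t).max() < 1e-10

    def test_sphere_to_ellipsoid_scaling(self, rng):
        u = rng.standard_normal((10, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        target = u * np.array([1.2, 1.0, 0.8])
        aff = G.fit_affine(u, target)
        assert np.allclose(aff.linear, np.diag([1.2, 1.0, 0.8]), atol=1e-9)

    def test_coplanar_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        with pytest.raises(G.DegenerateGeometryError):
            G.fit_affine(pts, pts)


class TestTriharmonicRBF:
    def test_identity_map(self, rng):
        S = rng.standard_normal((15, 3))
        rbf = G.fit_triharmonic_rbf(S, S)
        assert np.abs(rbf.weights).max() < 1e-10
        Q = rng.standard_normal((7, 3))
        assert np.abs(rbf.apply(Q) - Q).max() < 1e-9

    def test_affine_reproduction_off_controls(self, rng):
        S = rng.standard_normal((20, 3))
        A = np.eye(3) + 0.3 * rng.standard_normal((3, 3))
        t = rng.standard_normal(3)
        rbf = G.fit_triharmonic_rbf(S, S @ A.T + t)
        assert np.abs(rbf.weights).max() < 1e-10
        Q = rng.standard_normal((11, 3))
        assert np.abs(rbf.apply(Q) - (Q @ A.T + t)).max() < 1e-8

    def test_exact_interpolation_at_controls(self, rng):
        S = rng.standard_normal((20, 3))
        T = S + 0.1 * rng.standard_normal((20, 3))
        rbf = G.fit_triharmonic_rbf(S, T)
        assert np.abs(rbf.apply(S) - T).max() < 1e-9

    def test_duplicate_sources_named(self):
        S = np.zeros((5, 3))
        S[1:] = np.eye(4, 3)
        S[4] = S[1]
        with pytest.raises(ValueError, match=r"indices"):
            G.fit_triharmonic_rbf(S, S)


class TestMorphBone:
    def test_rigid_target_round_trips(self):
        src, tgt = generate_morph_pair("rigid", seed=3)
        morphed, rec = G.morph_bone(src, tgt)
        assert np.abs(morphed.vertices - src.vertices).max() < 1e-8

    def test_identity(self):
        src, tgt = generate_morph_pair("identity", seed=0)
        morphed, _ = G.morph_bone(src, tgt)
        assert np.abs(morphed.vertices - src.vertices).max() < 1e-9

    def test_uniform_scaling_about_centroid(self):
        src, tgt = generate_morph_pair("scale", seed=0)
        morphed, rec = G.morph_bone(src, tgt)
        c = src.vertices.mean(axis=0)
        expected = 1.1 * (src.vertices - c) + c
        assert np.abs(morphed.vertices - expected).max() < 1e-8
        assert np.abs(rec["rbf"].weights).max() < 1e-9

    def test_smooth_bump_interpolated_exactly(self):
        src, tgt = generate_morph_pair("bump", seed=5)
        _, rec = G.morph_bone(src, tgt)
        staged = rec["affine"].apply(src.vertices)
        assert np.abs(rec["rbf"].apply(staged) - tgt.vertices).max() < 1e-9

    def test_vertex_count_mismatch(self):
        src, tgt = generate_morph_pair("identity", seed=0)
        bad = G.SurfaceMesh(tgt.vertices[:-1], tgt.faces[:-4] % (len(tgt.vertices) - 1))
        with pytest.raises(ValueError, match="correspondence"):
            G.morph_bone(src, bad)


class TestSphereCircleFits:
    def test_exact_sphere_recovery(self, rng):
        c, r = np.array([1.0, 2.0, 3.0]), 0.04
        u = rng.standard_normal((60, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        cc, rr, rms = G.fit_sphere(c + r * u)
        assert np.abs(cc - c).max() < 1e-10 and abs(rr - r) < 1e-10 and rms < 1e-10

    def test_noisy_sphere_center_within_tolerance(self):
        c, r = np.array([0.1, -0.2, 0.05]), 0.04
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            u = rng.standard_normal((80, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            pts = c + (r + rng.normal(scale=1e-4, size=80))[:, None] * u
            cc, _, _ = G.fit_sphere(pts)
            errs.append(np.linalg.norm(cc - c))
        assert max(errs) < 1e-3

    def test_regular_tetrahedron_on_unit_sphere(self):
        pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3)
        cc, rr, _ = G.fit_sphere(pts)
        assert np.abs(cc).max() < 1e-12 and abs(rr - 1) < 1e-12

    def test_coplanar_sphere_degenerate(self):
        ang = np.linspace(0, 2 * np.pi, 9)[:-1]
        pts = np.stack([np.cos(ang), np.sin(ang), np.zeros(8)], axis=1)
        with pytest.raises(G.DegenerateGeometryError):
            G.fit_sphere(pts)

    def test_exact_circle_recovery(self):
        ang = np.linspace(0, 2 * np.pi, 17)[:-1]
        pts = np.stack([0.5 + 0.1 * np.cos(ang), -0.2 + 0.1 * np.sin(ang),
                        np.full(16, 0.3)], axis=1)
        c, r = G.fit_circle_in_plane(pts, [0, 0, 1.0])
        assert np.abs(c - [0.5, -0.2, 0.3]).max() < 1e-10 and abs(r - 0.1) < 1e-10

    def test_equilateral_triangle_circumcircle(self):
        ang = np.array([0, 2 * np.pi / 3, 4 * np.pi / 3])
        pts = np.stack([np.cos(ang), np.sin(ang), np.zeros(3)], axis=1)
        c, r = G.fit_circle_in_plane(pts, [0, 0, 1.0])
        assert np.abs(c).max() < 1e-12 and abs(r - 1) < 1e-12

    def test_hinge_axis_through_condylar_circles(self):
        ang = np.linspace(0, np.pi, 12)
        med = np.stack([np.full(12, 0.04), 0.3 + 0.035 * np.cos(ang),
                        0.1 + 0.035 * np.sin(ang)], axis=1)
        lat = med.copy()
        lat[:, 0] = -0.04
        origin, axis = G.hinge_axis_from_circles(med, lat, [1.0, 0, 0])
        assert np.allclose(origin, [0.0, 0.3, 0.1], atol=1e-10)
        assert np.allclose(np.abs(axis), [1, 0, 0], atol=1e-10)


class TestFEAFrame:
    def test_axis_aligned_case(self):
        fr = G.build_fea_frame([0.08, 0, 0], [0, 0, 0], [0.04, 0.4, 0])
        assert np.allclose(fr.origin, [0.04, 0, 0])
        assert np.allclose(fr.axes, np.eye(3), atol=1e-12)

    def test_equivariance_under_rigid_motion(self):
        rng = np.random.default_rng(1)
        med, lat, hip = [0.08, 0, 0], [0, 0, 0], [0.05, 0.4, 0.02]
        base = G.build_fea_frame(med, lat, hip)
        for _ in range(5):
            R = axis_angle(rng.standard_normal(3), rng.uniform(0, np.pi))
            t = rng.standard_normal(3)
            fr = G.build_fea_frame(R @ med + t, R @ lat + t, R @ hip + t)
            assert np.abs(fr.origin - (R @ base.origin + t)).max() < 1e-12
            assert np.abs(fr.axes - R @ base.axes).max() < 1e-12

    def test_hip_off_axis_reorthogonalised(self):
        fr = G.build_fea_frame([0.08, 0, 0], [0, 0, 0], [0.07, 0.4, 0])
        assert abs(np.linalg.norm(fr.axes[:, 1]) - 1) < 1e-12
        assert abs(fr.axes[:, 0] @ fr.axes[:, 1]) < 1e-12

    def test_collinear_inputs_rejected(self):
        with pytest.raises(G.DegenerateGeometryError):
            G.build_fea_frame([0.08, 0, 0], [0, 0, 0], [0.5, 0, 0])
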