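"""Projection-matrix construction, point projection, and DLT triangulation."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from spinepose.geometry import (
    CameraGeometry,
    DegenerateGeometryError,
    DegenerateProjectionError,
    GeometryError,
    ProjectionMatrix,
    build_projection,
    project_point,
    project_points,
    triangulate,
)


class TestBuildProjection:
    def test_isocenter_maps_to_principal_point(self, lumbar_ap):
        P = build_projection(lumbar_ap)
        assert np.allclose(project_point(P, (0, 0, 0)), (767.5, 511.5), atol=1e-9)

    def test_caudal_displacement_follows_similar_triangles(self, lumbar_ap):
        # magnification sdd/sad = 2, row spacing 300/1024 mm; 50 mm caudal
        P = build_projection(lumbar_ap)
        expected_v = 511.5 + 50.0 * (2000.0 / 1000.0) / (300.0 / 1024.0)
        uv = project_point(P, (0, 0, -50.0))
        assert np.allclose(uv, (767.5, expected_v), rtol=1e-12)

    def test_oblique_angles_project_symmetrically(self):
        # a point in the mirror plane of the ±15° assemblies (x = 0 for AP)
        common = dict(sdd_mm=2000, sad_mm=1000,
                      detector_size_mm=(450.0, 300.0), detector_pixels=(1536, 1024))
        x = np.array([0.0, 40.0, 10.0])
        u0 = project_point(build_projection(
            CameraGeometry("AP", lao_rao_deg=0.0, **common)), x)[0]
        u_pos = project_point(build_projection(
            CameraGeometry("AP", lao_rao_deg=15.0, **common)), x)[0]
        u_neg = project_point(build_projection(
            CameraGeometry("AP", lao_rao_deg=-15.0, **common)), x)[0]
        assert np.isclose(u_pos - u0, -(u_neg - u0), rtol=1e-9)

    def test_rotation_equivalence(self, lumbar_ap):
        # P(theta) equals P(0) right-multiplied by the world rotation
        theta = 12.5
        rotated = CameraGeometry("AP", 2000, 1000, theta,
                                 lumbar_ap.detector_size_mm, lumbar_ap.detector_pixels)
        P0 = build_projection(lumbar_ap).p
        Pt = build_projection(rotated).p
        th = np.deg2rad(theta)
        Rz = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        T = np.eye(4)
        T[:3, :3] = Rz.T  # world points rotate by -theta when the assembly rotates by +theta
        composed = P0 @ T
        assert np.allclose(Pt / np.linalg.norm(Pt), composed / np.linalg.norm(composed),
                           atol=1e-9)

    @pytest.mark.parametrize("bad", [
        dict(sdd_mm=1000, sad_mm=2000),      # sdd must exceed sad
        dict(sdd_mm=-2000, sad_mm=1000),
        dict(sdd_mm=np.nan, sad_mm=1000),
    ])
    def test_invalid_physical_parameters_rejected(self, bad):
        with pytest.raises(GeometryError):
            CameraGeometry("AP", lao_rao_deg=0.0,
                           detector_size_mm=(450.0, 300.0),
                           detector_pixels=(1536, 1024), **bad)

    def test_serialization_roundtrip(self, lumbar_ap):
        geom2 = CameraGeometry.from_dict(lumbar_ap.to_dict())
        assert geom2 == lumbar_ap
        P = build_projection(lumbar_ap)
        P2 = ProjectionMatrix.from_dict(P.to_dict())
        assert np.array_equal(P.p, P2.p)


class TestProjectPoint:
    def test_toy_dehomogenization(self):
        P = np.hstack([np.eye(3), np.zeros((3, 1))])
        assert np.allclose(project_point(P, (3.0, 4.0, 2.0)), (1.5, 2.0))

    def test_projective_invariance_along_ray(self):
        P = np.hstack([np.eye(3), np.zeros((3, 1))])
        x = np.array([3.0, 4.0, 2.0])
        assert np.allclose(project_point(P, x), project_point(P, 2 * x), rtol=1e-12)

    def test_degenerate_projection_raises(self, lumbar_ap):
        P = build_projection(lumbar_ap)
        # a point in the source plane has w ~ 0
        src = lumbar_ap.source_position()
        with pytest.raises(DegenerateProjectionError):
            project_point(P, src + np.array([5.0, 0.0, 0.0]))


class TestTriangulate:
    def test_noiseless_roundtrip_1000_points(self, lumbar_pair):
        P_ap, P_lat = lumbar_pair
        rng = np.random.default_rng(42)
        pts = rng.uniform(-125.0, 125.0, size=(1000, 3))
        uv_ap = project_points(P_ap, pts)
        uv_lat = project_points(P_lat, pts)
        for x, a, b in zip(pts, uv_ap, uv_lat):
            rec = triangulate([(P_ap, a), (P_lat, b)])
            assert np.linalg.norm(rec - x) <= 1e-6

    def test_magnification_law(self, lumbar_ap):
        # d mm in the detector-parallel plane moves d*(sdd/sad)/spacing pixels
        P = build_projection(lumbar_ap)
        d = 37.5
        base = project_point(P, (0.0, 0.0, 0.0))
        moved = project_point(P, (d, 0.0, 0.0))
        expected = d * (2000.0 / 1000.0) / (450.0 / 1536.0)
        assert np.isclose(moved[0] - base[0], expected, rtol=1e-9)

    def test_matches_nonlinear_reprojection_oracle_under_pixel_noise(self, lumbar_pair):
        P_ap, P_lat = lumbar_pair
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.uniform(-100, 100, size=3)
            obs = []
            for P in lumbar_pair:
                uv = project_point(P, x) + rng.uniform(-1.0, 1.0, size=2)
                obs.append((P, uv))
            dlt = triangulate(obs)

            def resid(p):
                return np.concatenate([project_point(P, p) - uv for P, uv in obs])

            opt = least_squares(resid, x0=np.zeros(3), method="lm").x
            assert np.linalg.norm(dlt - opt) <= 0.3

    def test_identical_views_degenerate(self, lumbar_pair):
        P_ap, _ = lumbar_pair
        uv = project_point(P_ap, (1.0, 2.0, 3.0))
        with pytest.raises(DegenerateGeometryError):
            triangulate([(P_ap, uv), (P_ap, uv)])

    def test_requires_two_observations(self, lumbar_pair):
        P_ap, _ = lumbar_pair
        with pytest.raises(ValueError):
            triangulate([(P_ap, (0.0, 0.0))])
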