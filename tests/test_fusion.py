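"""Voxel cube anchoring, projective unprojection, and weighted aggregation."""

import numpy as np
import pytest

from spinepose.autodiff import Tensor
from spinepose.fusion import FeatureVolume, VoxelCube, aggregate, make_cube, unproject
from spinepose.geometry import CameraGeometry, build_projection, project_point


def closest_point_between_rays(o1, d1, o2, d2):
    """Midpoint of the common perpendicular of two skew rays (oracle)."""
    d1 = d1 / np.linalg.norm(d1)
    d2 = d2 / np.linalg.norm(d2)
    w0 = o1 - o2
    a, b, c = d1 @ d1, d1 @ d2, d2 @ d2
    d, e = d1 @ w0, d2 @ w0
    denom = a * c - b * b
    t1 = (b * e - c * d) / denom
    t2 = (a * e - b * d) / denom
    return 0.5 * (o1 + t1 * d1 + o2 + t2 * d2)


def _splat_bilinear(img, uv):
    """Adjoint of bilinear sampling: distribute a unit impulse at uv."""
    u, v = uv
    x0, y0 = int(np.floor(u)), int(np.floor(v))
    fx, fy = u - x0, v - y0
    for dy in (0, 1):
        for dx in (0, 1):
            img[y0 + dy, x0 + dx] += (fx if dx else 1 - fx) * (fy if dy else 1 - fy)


def backprojected_ray(geom: CameraGeometry, uv):
    """Ray through the source and a detector pixel (pixel-centre convention)."""
    su, sv = geom.pixel_spacing_mm
    n_cols, n_rows = geom.detector_pixels
    u_axis, v_axis = geom.detector_axes()
    pix = (geom.detector_center()
           + (uv[0] - (n_cols - 1) / 2) * su * u_axis
           + (uv[1] - (n_rows - 1) / 2) * sv * v_axis)
    src = geom.source_position()
    return src, pix - src


class TestVoxelCube:
    def test_voxel_size(self):
        cube = VoxelCube(center_mm=(0, 0, 0), side_mm=250.0, resolution=64)
        assert cube.voxel_size_mm == 3.90625

    def test_voxel_centres_span(self):
        cube = VoxelCube(center_mm=(10.0, 0.0, -5.0), side_mm=100.0, resolution=4)
        xs = cube.axis_coords(0)
        assert np.allclose(xs, [10 - 37.5, 10 - 12.5, 10 + 12.5, 10 + 37.5])

    def test_world_index_roundtrip(self):
        cube = VoxelCube(center_mm=(1.0, 2.0, 3.0), side_mm=80.0, resolution=16)
        pts = cube.voxel_centers()[[0, 100, 4095]]
        idx = cube.world_to_index(pts)
        d = cube.resolution
        expected = np.stack(np.unravel_index([0, 100, 4095], (d, d, d)), axis=1)
        assert np.allclose(idx, expected, atol=1e-9)

    def test_invalid_resolution(self):
        with pytest.raises(ValueError):
            VoxelCube(center_mm=(0, 0, 0), resolution=1)


class TestMakeCube:
    def test_symmetric_views_centre_at_isocenter(self, lumbar_pair):
        P_ap, P_lat = lumbar_pair
        shape = (1024, 1536)
        cube = make_cube(P_ap, P_lat, (shape, shape))
        assert np.linalg.norm(np.asarray(cube.center_mm)) <= 1e-6

    def test_oblique_views_match_ray_midpoint_oracle(self):
        common = dict(sdd_mm=2000, sad_mm=1000,
                      detector_size_mm=(450.0, 300.0), detector_pixels=(1536, 1024))
        g_ap = CameraGeometry("AP", lao_rao_deg=15.0, **common)
        g_lat = CameraGeometry("LAT", lao_rao_deg=-15.0, **common)
        shape = (1024, 1536)
        centre_uv = ((1536 - 1) / 2, (1024 - 1) / 2)
        cube = make_cube(build_projection(g_ap), build_projection(g_lat),
                         (shape, shape))
        o1, d1 = backprojected_ray(g_ap, centre_uv)
        o2, d2 = backprojected_ray(g_lat, centre_uv)
        oracle = closest_point_between_rays(o1, d1, o2, d2)
        assert np.linalg.norm(np.asarray(cube.center_mm) - oracle) <= 1e-6


class TestUnproject:
    def test_constant_image_fills_cube(self, lumbar_pair):
        # cube small enough to project fully inside the detector bounds
        # (the 300 mm detector at 2x magnification images |z| < 75 mm)
        P_ap, _ = lumbar_pair
        cube = VoxelCube(center_mm=(0.0, 0.0, 0.0), side_mm=120.0, resolution=8)
        M = Tensor(np.full((2, 1024, 1536), 3.25, dtype=np.float32))
        vol = unproject(M, P_ap, cube)
        assert np.allclose(vol.values.data, 3.25)

    def test_fused_one_hot_peaks_at_true_point(self, lumbar_pair):
        # a unit impulse splat bilinearly at each view's projection of p:
        # sampling the splat is the triangle-kernel autocorrelation, which
        # peaks at zero offset, so the fused volume peaks at the voxel of p
        P_ap, P_lat = lumbar_pair
        cube = VoxelCube(center_mm=(0.0, 0.0, 0.0), side_mm=140.0, resolution=32)
        rng = np.random.default_rng(11)
        w = [Tensor(np.ones(1)), Tensor(np.ones(1))]
        for _ in range(50):
            idx = rng.integers(0, 32, size=3)
            p = np.array([cube.axis_coords(a)[idx[a]] for a in range(3)])
            vols = []
            for P in (P_ap, P_lat):
                uv = project_point(P, p)
                img = np.zeros((1, 1024, 1536))
                _splat_bilinear(img[0], uv)
                vols.append(unproject(Tensor(img), P, cube))
            fused = aggregate(vols, w)
            peak = np.unravel_index(np.argmax(fused.values.data[0]), (32, 32, 32))
            assert np.all(np.abs(np.asarray(peak) - idx) <= 1.0)

    def test_off_image_voxels_are_zero(self, lumbar_pair):
        P_ap, _ = lumbar_pair
        # cube shifted far laterally: part of it projects off the detector
        cube = VoxelCube(center_mm=(330.0, 0.0, 0.0), side_mm=200.0, resolution=8)
        M = Tensor(np.ones((1, 1024, 1536), dtype=np.float32))
        vol = unproject(M, P_ap, cube).values.data[0]
        uv = project_point(P_ap, cube.voxel_centers())
        inside = ((uv[:, 0] > -1) & (uv[:, 0] < 1536) &
                  (uv[:, 1] > -1) & (uv[:, 1] < 1024)).reshape(8, 8, 8)
        assert np.any(~inside)
        assert np.all(vol[~inside] == 0.0)
        strict = ((uv[:, 0] >= 0) & (uv[:, 0] <= 1535) &
                  (uv[:, 1] >= 0) & (uv[:, 1] <= 1023)).reshape(8, 8, 8)
        assert np.all(vol[strict] > 0.0)

    def test_linearity_exact(self, lumbar_pair):
        P_ap, _ = lumbar_pair
        cube = VoxelCube(center_mm=(0.0, 0.0, 0.0), side_mm=200.0, resolution=8)
        rng = np.random.default_rng(2)
        A = rng.normal(size=(2, 1024, 1536)).astype(np.float64)
        B = rng.normal(size=(2, 1024, 1536)).astype(np.float64)
        lhs = unproject(Tensor(3.0 * A - 2.0 * B), P_ap, cube).values.data
        rhs = (3.0 * unproject(Tensor(A), P_ap, cube).values.data
               - 2.0 * unproject(Tensor(B), P_ap, cube).values.data)
        assert np.allclose(lhs, rhs, rtol=1e-12, atol=1e-12)


class TestAggregate:
    def _two_volumes(self, K=3, D=4, seed=0):
        rng = np.random.default_rng(seed)
        cube = VoxelCube(center_mm=(0.0, 0.0, 0.0), side_mm=100.0, resolution=D)
        A = FeatureVolume(Tensor(rng.normal(size=(K, D, D, D))), cube)
        B = FeatureVolume(Tensor(rng.normal(size=(K, D, D, D))), cube)
        return A, B

    def test_equal_weights_give_mean(self):
        A, B = self._two_volumes()
        w = [Tensor(np.full(3, 2.0)), Tensor(np.full(3, 2.0))]
        agg = aggregate([A, B], w)
        assert np.allclose(agg.values.data, (A.values.data + B.values.data) / 2, rtol=1e-6)

    def test_weights_two_one(self):
        A, B = self._two_volumes(seed=1)
        w = [Tensor(np.full(3, 2.0)), Tensor(np.full(3, 1.0))]
        agg = aggregate([A, B], w)
        assert np.allclose(agg.values.data,
                           (2 * A.values.data + B.values.data) / 3, rtol=1e-6)

    def test_vanishing_weight_limit_returns_first_volume(self):
        A, B = self._two_volumes(seed=2)
        w = [Tensor(np.full(3, 1.0)), Tensor(np.full(3, 1e-9))]
        agg = aggregate([A, B], w)
        assert np.allclose(agg.values.data, A.values.data, atol=1e-6)

    def test_convexity(self):
        A, B = self._two_volumes(seed=3)
        rng = np.random.default_rng(4)
        w = [Tensor(rng.uniform(0.1, 5.0, size=3)), Tensor(rng.uniform(0.1, 5.0, size=3))]
        agg = aggregate([A, B], w).values.data
        lo = np.minimum(A.values.data, B.values.data)
        hi = np.maximum(A.values.data, B.values.data)
        assert np.all(agg >= lo - 1e-9) and np.all(agg <= hi + 1e-9)

    def test_nonpositive_weights_rejected(self):
        A, B = self._two_volumes()
        with pytest.raises(ValueError):
            aggregate([A, B], [Tensor(np.zeros(3)), Tensor(np.ones(3))])


def test_gradient_of_fused_unprojection_matches_finite_differences(lumbar_pair):
    """Numerical vs analytic gradient of aggregate(unproject(M)) w.r.t. M."""
    P_ap, P_lat = lumbar_pair
    cube = VoxelCube(center_mm=(0.0, 0.0, 0.0), side_mm=150.0, resolution=4)
    rng = np.random.default_rng(5)
    # tiny images spanning the projected cube region
    M0 = rng.normal(size=(2, 1024, 1536))
    target = rng.normal(size=(2, 4, 4, 4))
    w = [Tensor(np.array([1.5, 0.5])), Tensor(np.array([1.0, 2.0]))]

    def loss_of(Mnp, track=False):
        M = Tensor(Mnp.copy())
        M.requires_grad = track
        va = unproject(M, P_ap, cube)
        vb = unproject(M, P_lat, cube)
        agg = aggregate([va, vb], w)
        loss = ((agg.values - Tensor(target)) ** 2).sum()
        return loss, M

    loss, M = loss_of(M0, track=True)
    loss.backward()
    # probe the pixels that actually receive gradient
    idx = np.argwhere(np.abs(M.grad) > 1e-6)[:6]
    for c, r, s in idx:
        eps = 1e-5
        hi, lo = M0.copy(), M0.copy()
        hi[c, r, s] += eps
        lo[c, r, s] -= eps
        num = (float(loss_of(hi)[0].data) - float(loss_of(lo)[0].data)) / (2 * eps)
        assert np.isclose(M.grad[c, r, s], num, rtol=1e-4)
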