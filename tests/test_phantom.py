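"""Phantom construction, DRR rendering, pose sampling, and dataset plumbing."""

import numpy as np
import pytest

from spinepose.geometry import GeometryError, build_projection, project_point
from spinepose.phantom import (
    AcquisitionConfig,
    ConfigurationError,
    PhantomConfig,
    PhantomVolume,
    downscale_sample,
    generate_dataset,
    gt_heatmaps_2d,
    load_sample,
    make_phantom,
    render_drr,
    sample_pose_pair,
)


class TestMakePhantom:
    def test_landmark_count_and_gap_range(self):
        ph = make_phantom(5, seed=1)
        assert ph.landmarks_mm.shape == (5, 3)
        gaps = np.diff(ph.landmarks_mm[:, 2])
        assert np.all(gaps >= 30.0) and np.all(gaps <= 40.0)  # caudal -> cranial

    def test_z_span_matches_sum_of_gaps(self):
        # four vertebrae -> three gaps of 30-40 mm each
        ph = make_phantom(4, seed=5)
        span = ph.landmarks_mm[-1, 2] - ph.landmarks_mm[0, 2]
        assert 3 * 30.0 <= span <= 3 * 40.0

    def test_deterministic_in_seed(self):
        a = make_phantom(3, seed=9)
        b = make_phantom(3, seed=9)
        assert np.array_equal(a.attenuation, b.attenuation)
        assert np.array_equal(a.landmarks_mm, b.landmarks_mm)
        c = make_phantom(3, seed=10)
        assert not np.array_equal(a.landmarks_mm, c.landmarks_mm)

    def test_landmarks_inside_volume(self):
        ph = make_phantom(5, seed=3)
        lo, hi = ph.bounds_mm
        assert np.all(ph.landmarks_mm > lo) and np.all(ph.landmarks_mm < hi)

    def test_oversized_stack_rejected(self):
        with pytest.raises(ConfigurationError):
            make_phantom(8, seed=0)  # 7 gaps of >=30 mm exceed the 192 mm grid


class TestRenderDRR:
    def test_zero_attenuation_renders_zero(self, tiny_config):
        ph = make_phantom(3, seed=7, config=tiny_config.phantom)
        ph.attenuation[:] = 0.0
        geom, _ = sample_pose_pair(0, tiny_config.acquisition)
        raw = render_drr(ph, geom, step_mm=2.0, normalize=False)
        assert np.all(raw == 0.0)

    def test_dense_sphere_peaks_at_projection(self, tiny_config):
        # a single small dense sphere: image maximum within 1 px of P(x)
        cfg = tiny_config.phantom
        shape = np.array(cfg.grid_shape)
        spacing = np.full(3, cfg.voxel_spacing_mm)
        origin = -(shape * spacing) / 2 + spacing / 2
        center = np.array([12.0, -8.0, 20.0])
        ax = [origin[i] + spacing[i] * np.arange(shape[i]) for i in range(3)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        att = (((X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2)
               <= 6.0 ** 2).astype(np.float32)
        ph = PhantomVolume(att, spacing, origin, center[None])
        geom, _ = sample_pose_pair(5, tiny_config.acquisition)
        img = render_drr(ph, geom, step_mm=2.0)
        peak = np.unravel_index(np.argmax(img), img.shape)  # (row, col)
        uv = project_point(build_projection(geom), center)
        assert abs(peak[1] - uv[0]) <= 1.0 and abs(peak[0] - uv[1]) <= 1.0

    def test_integral_linear_in_attenuation(self, tiny_config):
        ph = make_phantom(3, seed=7, config=tiny_config.phantom)
        geom, _ = sample_pose_pair(1, tiny_config.acquisition)
        raw = render_drr(ph, geom, step_mm=2.0, normalize=False)
        ph2 = PhantomVolume(2.0 * ph.attenuation, ph.voxel_spacing_mm,
                            ph.origin_mm, ph.landmarks_mm)
        raw2 = render_drr(ph2, geom, step_mm=2.0, normalize=False)
        assert np.allclose(raw2, 2.0 * raw, rtol=1e-5, atol=1e-5)

    def test_step_halving_converges(self, tiny_config):
        ph = make_phantom(3, seed=7, config=tiny_config.phantom)
        geom, _ = sample_pose_pair(1, tiny_config.acquisition)
        coarse = render_drr(ph, geom, step_mm=2.0, normalize=False)
        fine = render_drr(ph, geom, step_mm=1.0, normalize=False)
        # integration error shrinks with the step: mean deviation small
        scale = np.abs(fine).max()
        assert np.abs(coarse - fine).mean() / scale < 0.01

    def test_source_inside_volume_rejected(self, tiny_config):
        ph = make_phantom(3, seed=7, config=tiny_config.phantom)
        huge = PhantomVolume(ph.attenuation, ph.voxel_spacing_mm * 100,
                             ph.origin_mm * 100, ph.landmarks_mm)
        geom, _ = sample_pose_pair(0, tiny_config.acquisition)
        with pytest.raises(GeometryError):
            render_drr(huge, geom)


class TestPosePair:
    def test_distribution_of_angles(self):
        angles = []
        for seed in range(2000):
            ap, lat = sample_pose_pair(seed)
            angles += [ap.lao_rao_deg, lat.lao_rao_deg]
        angles = np.asarray(angles)
        assert angles.min() >= -15.0 and angles.max() <= 15.0
        assert abs(angles.mean()) < 0.5

    def test_deterministic(self):
        a = sample_pose_pair(123)
        b = sample_pose_pair(123)
        assert a == b

    def test_zero_range_gives_nominal_views(self):
        cfg = AcquisitionConfig(angle_range_deg=0.0)
        ap, lat = sample_pose_pair(0, cfg)
        assert ap.assembly_angle_deg == 0.0
        assert lat.assembly_angle_deg == 90.0


class TestHeatmaps:
    def test_peak_one_at_landmark_pixel(self):
        hm = gt_heatmaps_2d(np.array([[10.0, 20.0]]), (32, 32), sigma_px=2.0)
        assert hm.values[20, 10, 0] == 1.0
        assert hm.values.max() == 1.0

    def test_value_at_one_sigma(self):
        sigma = 3.0
        hm = gt_heatmaps_2d(np.array([[16.0, 16.0]]), (32, 32), sigma)
        assert np.isclose(hm.values[16, 19, 0], np.exp(-0.5), rtol=1e-12)

    def test_off_image_landmark_finite_below_one(self):
        hm = gt_heatmaps_2d(np.array([[-5.0, -9.0]]), (16, 16), sigma_px=4.0)
        assert np.all(np.isfinite(hm.values))
        assert hm.values.max() < 1.0

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gt_heatmaps_2d(np.zeros((1, 2)), (8, 8), 0.0)


class TestDownscale:
    def test_reprojection_invariant_preserved(self, tiny_sample):
        small = downscale_sample(tiny_sample, 2)
        small.validate(atol_px=1e-6)
        assert small.image_ap.shape == (32, 32)
        # pooling preserves total intensity
        assert np.isclose(small.image_ap.mean(), tiny_sample.image_ap.mean(), rtol=1e-5)

    def test_factor_one_is_identity(self, tiny_sample):
        assert downscale_sample(tiny_sample, 1) is tiny_sample


@pytest.fixture(scope="module")
def dataset(tmp_path_factory, tiny_config):
    out = tmp_path_factory.mktemp("ds")
    manifest = generate_dataset(out, seed=77, config=tiny_config)
    return out, manifest


class TestGenerateDataset:
    def test_split_grouping_by_phantom(self, dataset):
        _, manifest = dataset
        per_phantom = manifest.groupby("phantom_id")["split"].nunique()
        assert (per_phantom == 1).all()
        assert set(manifest["split"]) == {"train", "val", "test"}

    def test_regeneration_reproduces_hashes(self, dataset, tmp_path, tiny_config):
        _, manifest = dataset
        manifest2 = generate_dataset(tmp_path / "again", seed=77, config=tiny_config)
        assert list(manifest2["hash"]) == list(manifest["hash"])

    def test_written_samples_satisfy_invariants(self, dataset):
        out, manifest = dataset
        for row in manifest.itertuples():
            sample = load_sample(out / row.json)
            sample.validate(atol_px=1e-5)  # float32 TIFF round trip
            # radio-dense bodies: landmark projections brighter than median
            for img, lm2d in ((sample.image_ap, sample.landmarks_2d_px_ap),
                              (sample.image_lat, sample.landmarks_2d_px_lat)):
                med = np.median(img)
                for u, v in lm2d:
                    assert img[int(round(v)), int(round(u))] > med
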