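"""PE/IPE/IDrate metrics, cumulative curves, and the triangulation baseline."""

import numpy as np
import pytest

from spinepose.evaluation import (baseline_triangulation, compute_metrics,
                                  cumulative_ipe, point_error, write_report)
from spinepose.geometry import triangulate
from spinepose.phantom import gt_heatmaps_2d
from spinepose.scn2d import FeatureMap2D, FusionWeights, Heatmaps2DPredicted, detect_2d


class TestPointError:
    def test_identical_points_give_zero(self):
        x = np.arange(12.0).reshape(4, 3)
        assert np.all(point_error(x, x) == 0)

    def test_three_four_five(self):
        assert point_error([[3.0, 4.0, 0.0]], [[0.0, 0.0, 0.0]])[0] == 5.0

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 50, 3))
        oracle = np.sqrt(((a - b) ** 2).sum(axis=1))
        assert np.allclose(point_error(a, b), oracle, atol=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            point_error(np.zeros((2, 3)), np.zeros((3, 3)))


class TestComputeMetrics:
    def test_hand_computed_example(self):
        # one image, five landmarks at distances (1, 2, 3, 6, 10) mm
        gt = np.zeros((5, 3))
        pred = np.zeros((5, 3))
        pred[:, 0] = [1, 2, 3, 6, 10]
        rep = compute_metrics([pred], [gt])
        assert rep.id_rate_pct == 60.0
        assert np.isclose(rep.ipe_per_image[0], 4.4)
        assert np.isclose(rep.pe_all_mean_mm, 4.4)

    def test_perfect_predictions(self):
        gt = [np.random.default_rng(1).normal(size=(4, 3)) for _ in range(3)]
        rep = compute_metrics([g.copy() for g in gt], gt)
        assert rep.id_rate_pct == 100.0
        assert rep.pe_all_mean_mm == 0.0 and rep.pe_all_sd_mm == 0.0

    def test_boundary_exactly_five_mm_not_identified(self):
        gt = np.zeros((1, 3))
        pred = np.array([[5.0, 0.0, 0.0]])  # strictly "below 5.0" required
        rep = compute_metrics([pred], [gt])
        assert rep.id_rate_pct == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n_img = rng.integers(1, 6)
            L = rng.integers(1, 5)
            preds = [rng.normal(scale=4.0, size=(L, 3)) for _ in range(n_img)]
            gts = [rng.normal(scale=4.0, size=(L, 3)) for _ in range(n_img)]
            rep = compute_metrics(preds, gts)
            # double-loop oracle
            dists, ident, total = [], 0, 0
            for p, g in zip(preds, gts):
                for pl, gl in zip(p, g):
                    d = float(np.sqrt(((pl - gl) ** 2).sum()))
                    dists.append(d)
                    total += 1
                    if d < 5.0:
                        ident += 1
            assert np.isclose(rep.pe_all_mean_mm, np.mean(dists), rtol=1e-12)
            assert np.isclose(rep.pe_all_sd_mm, np.std(dists), rtol=1e-9, atol=1e-12)
            assert np.isclose(rep.id_rate_pct, 100.0 * ident / total, rtol=1e-12)

    def test_missing_landmarks_counted_against_idrate(self):
        gt = np.zeros((2, 3))
        pred = np.array([[0.0, 0.0, 0.0], [np.nan, np.nan, np.nan]])
        rep = compute_metrics([pred], [gt])
        assert rep.id_rate_pct == 50.0
        assert rep.n_missing == 1
        assert rep.pe_all_mean_mm == 0.0  # missing excluded from PE stats

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([], [])


class TestCumulativeIPE:
    def test_simple_fractions(self):
        curve = cumulative_ipe([1.0, 2.0, 3.0], [1.5, 2.5, 3.5])
        assert np.allclose(curve["fraction"], [1 / 3, 2 / 3, 1.0])

    def test_constant_ipe_step(self):
        curve = cumulative_ipe([2.0, 2.0], [1.0, 2.0, 3.0])
        assert np.allclose(curve["fraction"], [0.0, 1.0, 1.0])

    def test_monotone_and_matches_counting_oracle(self):
        rng = np.random.default_rng(3)
        ipe = rng.uniform(0, 10, size=40)
        grid = np.linspace(0, 11, 23)
        curve = cumulative_ipe(ipe, grid)
        frac = curve["fraction"].to_numpy()
        assert np.all(np.diff(frac) >= 0)
        assert frac[-1] == 1.0
        for t, f in zip(grid, frac):
            assert np.isclose(f, np.sum(ipe <= t) / len(ipe), rtol=1e-12)


class _MockExtractor:
    """Duck-typed 2D model emitting prescribed ground-truth heatmaps."""

    def __init__(self, heatmaps_by_key):
        self.heatmaps = heatmaps_by_key

    def extract(self, image):
        h = self.heatmaps[image.tobytes()]
        L = h.shape[-1]
        K = 2
        return (FeatureMap2D(np.zeros(image.shape + (K,))),
                Heatmaps2DPredicted(h=h, h_la=h, h_sc=np.ones_like(h)),
                FusionWeights(np.ones(K)))


class TestBaselineTriangulation:
    def test_exact_heatmap_peaks_recover_landmarks(self, tiny_sample):
        s = tiny_sample
        mock = _MockExtractor({
            s.image_ap.tobytes(): gt_heatmaps_2d(s.landmarks_2d_px_ap,
                                                 s.image_ap.shape, 1.5).values,
            s.image_lat.tobytes(): gt_heatmaps_2d(s.landmarks_2d_px_lat,
                                                  s.image_lat.shape, 1.5).values,
        })
        pred = baseline_triangulation(s, mock, standardize=False)
        err = point_error(pred.y_mm, s.landmarks_3d_mm)
        # argmax discretization: at most half a pixel per view; pixel
        # footprint at the isocenter is spacing / magnification
        su = s.geom_ap.pixel_spacing_mm[0]
        mag = s.geom_ap.sdd_mm / s.geom_ap.sad_mm
        assert np.all(err <= su / mag)

    def test_matches_manual_triangulation_of_argmax_pixels(self, tiny_sample):
        s = tiny_sample
        h_ap = gt_heatmaps_2d(s.landmarks_2d_px_ap, s.image_ap.shape, 1.5).values
        h_lat = gt_heatmaps_2d(s.landmarks_2d_px_lat, s.image_lat.shape, 1.5).values
        mock = _MockExtractor({s.image_ap.tobytes(): h_ap,
                               s.image_lat.tobytes(): h_lat})
        pred = baseline_triangulation(s, mock, standardize=False)
        ca, _ = detect_2d(h_ap)
        cl, _ = detect_2d(h_lat)
        for l in range(len(ca)):
            manual = triangulate([(s.P_ap, ca[l]), (s.P_lat, cl[l])])
            assert np.allclose(pred.y_mm[l], manual, atol=1e-9)

    def test_undetected_view_propagates_missing(self, tiny_sample):
        s = tiny_sample
        h_ap = gt_heatmaps_2d(s.landmarks_2d_px_ap, s.image_ap.shape, 1.5).values
        h_lat = gt_heatmaps_2d(s.landmarks_2d_px_lat, s.image_lat.shape, 1.5).values
        h_lat[:, :, 1] = 0.0  # landmark 1 invisible in the lateral view
        mock = _MockExtractor({s.image_ap.tobytes(): h_ap,
                               s.image_lat.tobytes(): h_lat})
        pred = baseline_triangulation(s, mock, standardize=False)
        assert np.all(np.isnan(pred.y_mm[1]))
        assert np.all(np.isfinite(pred.y_mm[[0, 2]]))


class TestWriteReport:
    def test_outputs_deterministic_and_consistent(self, tmp_path):
        rng = np.random.default_rng(4)
        preds = [rng.normal(scale=3.0, size=(3, 3)) for _ in range(5)]
        gts = [rng.normal(scale=3.0, size=(3, 3)) for _ in range(5)]
        rep = compute_metrics(preds, gts)
        p1 = write_report(rep, tmp_path / "a")
        p2 = write_report(rep, tmp_path / "b")
        assert p1["metrics_json"].read_bytes() == p2["metrics_json"].read_bytes()
        assert p1["curve_csv"].read_bytes() == p2["curve_csv"].read_bytes()
        # report totals equal recomputation from the per-image records
        assert np.isclose(np.mean(rep.ipe_per_image),
                          np.mean([point_error(p, g).mean()
                                   for p, g in zip(preds, gts)]))
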