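"""Localization metrics and the coordinate-level triangulation baseline.

Metrics follow the standard landmark-localization conventions:

* **PE** — per-landmark point error, the Euclidean distance (mm) between
  predicted and ground-truth positions; pooled mean/SD over every landmark
  of every test image is reported as ``PEall``.
* **IPE** — image-specific point error, the mean PE of one image; its
  cumulative distribution curve shows the fraction of images at or below a
  threshold.
* **IDrate** — the percentage of landmarks whose PE is strictly below the
  identification threshold (5.0 mm by default).

The triangulation baseline localizes each landmark independently per view by
heatmap argmax and lifts the pair to 3D by DLT triangulation — the
coordinate-level alternative the feature-level fusion pipeline is compared
against. Landmark correspondence is positional throughout (channel l is
landmark l); a landmark undetected in either view is scored as not
identified and excluded from PE averages (the exclusion count is reported).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import triangulate
from .phantom import BiplanarSample
from .regress3d import LandmarkPrediction
from .scn2d import SCN2D, detect_2d

__all__ = [
    "MetricsReport",
    "point_error",
    "compute_metrics",
    "cumulative_ipe",
    "baseline_triangulation",
    "write_report",
]


@dataclass
class MetricsReport:
    """Summary metrics over a test set."""

    pe_all_mean_mm: float
    pe_all_sd_mm: float
    ipe_per_image: list[float]
    id_rate_pct: float
    threshold_mm: float
    n_landmarks: int
    n_images: int
    n_missing: int = 0

    def to_dict(self) -> dict:
        return {
            "pe_all_mean_mm": self.pe_all_mean_mm,
            "pe_all_sd_mm": self.pe_all_sd_mm,
            "id_rate_pct": self.id_rate_pct,
            "threshold_mm": self.threshold_mm,
            "n_landmarks": self.n_landmarks,
            "n_images": self.n_images,
            "n_missing": self.n_missing,
            "ipe_per_image": list(map(float, self.ipe_per_image)),
        }

    def summary(self) -> str:
        return (
            f"IDrate {self.id_rate_pct:.2f}% @ {self.threshold_mm:g} mm | "
            f"PEall {self.pe_all_mean_mm:.2f} ± {self.pe_all_sd_mm:.2f} mm | "
            f"{self.n_images} images, {self.n_landmarks} landmarks"
            + (f", {self.n_missing} missing" if self.n_missing else "")
        )


def point_error(pred: np.ndarray, gt: np.ndarray) -> np.ndarray:
    """Per-landmark Euclidean distances (mm); ordering is positional."""
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    gt = np.atleast_2d(np.asarray(gt, dtype=float))
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    return np.linalg.norm(pred - gt, axis=1)


def compute_metrics(predictions: list[np.ndarray], ground_truths: list[np.ndarray],
                    threshold_mm: float = 5.0) -> MetricsReport:
    """Pool PE/IPE/IDrate over a list of per-image (L, 3) arrays.

    Predictions may contain NaN rows for missing landmarks: these count
    against the IDrate (a missing landmark is never identified) but are
    excluded from the PE statistics, with the exclusion count reported.
    """
    if len(predictions) == 0 or len(predictions) != len(ground_truths):
        raise ValueError("need equal, nonzero numbers of predictions and ground truths")
    all_pe = []
    ipe = []
    n_total = 0
    n_missing = 0
    n_identified = 0
    for pred, gt in zip(predictions, ground_truths):
        pred = np.atleast_2d(np.asarray(pred, dtype=float))
        gt = np.atleast_2d(np.asarray(gt, dtype=float))
        missing = np.any(~np.isfinite(pred), axis=1)
        n_total += len(gt)
        n_missing += int(missing.sum())
        pe = point_error(np.where(missing[:, None], 0.0, pred), gt)
        valid_pe = pe[~missing]
        n_identified += int((valid_pe < threshold_mm).sum())  # strict "below"
        all_pe.extend(valid_pe)
        ipe.append(float(valid_pe.mean()) if len(valid_pe) else float("inf"))
    all_pe = np.asarray(all_pe)
    return MetricsReport(
        pe_all_mean_mm=float(all_pe.mean()) if len(all_pe) else float("nan"),
        pe_all_sd_mm=float(all_pe.std(ddof=0)) if len(all_pe) else float("nan"),
        ipe_per_image=ipe,
        id_rate_pct=100.0 * n_identified / n_total,
        threshold_mm=threshold_mm,
        n_landmarks=n_total,
        n_images=len(predictions),
        n_missing=n_missing,
    )


def cumulative_ipe(ipe_per_image: np.ndarray | list[float],
                   grid_mm: np.ndarray | list[float]) -> pd.DataFrame:
    """Cumulative IPE curve: fraction of images with IPE <= each threshold.

    Returns a DataFrame with columns ``threshold_mm`` and ``fraction``; the
    curve is a monotone nondecreasing right-continuous step function that
    reaches 1 once the grid covers the largest IPE.
    """
    ipe = np.asarray(ipe_per_image, dtype=float)
    if len(ipe) == 0:
        raise ValueError("empty IPE list")
    grid = np.asarray(grid_mm, dtype=float)
    frac = (ipe[None, :] <= grid[:, None]).mean(axis=1)
    return pd.DataFrame({"threshold_mm": grid, "fraction": frac})


def baseline_triangulation(sample: BiplanarSample, model2d: SCN2D,
                           standardize: bool = True) -> LandmarkPrediction:
    """Coordinate-level baseline: per-view 2D argmax then DLT triangulation.

    Runs the shared 2D extractor on both views, reads out per-channel argmax
    pixel coordinates, and triangulates each landmark independently. A
    channel with no response in either view yields a NaN (missing) landmark.
    """
    coords = {}
    detected = {}
    for view, image, P in (("ap", sample.image_ap, sample.P_ap),
                           ("lat", sample.image_lat, sample.P_lat)):
        img = _standardize(image) if standardize else image
        _, heat, _ = model2d.extract(img)
        coords[view], detected[view] = detect_2d(heat)
    L = len(coords["ap"])
    y = np.full((L, 3), np.nan)
    conf = np.zeros(L)
    for l in range(L):
        if detected["ap"][l] and detected["lat"][l]:
            y[l] = triangulate([
                (sample.P_ap, coords["ap"][l]),
                (sample.P_lat, coords["lat"][l]),
            ])
            conf[l] = 1.0
    return LandmarkPrediction(y_mm=y, confidence=conf, sample_id=sample.sample_id)


def _standardize(image: np.ndarray) -> np.ndarray:
    m = float(image.mean())
    s = float(image.std())
    return (image - m) / (s + 1e-8)


def write_report(report: MetricsReport, out_dir: str | Path,
                 curve_grid_mm: np.ndarray | None = None,
                 per_image_ids: list[str] | None = None) -> dict[str, Path]:
    """Write metrics JSON + CSV and the cumulative IPE curve CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    mj = out_dir / "metrics.json"
    mj.write_text(json.dumps(report.to_dict(), indent=1))
    paths["metrics_json"] = mj
    mc = out_dir / "metrics_per_image.csv"
    pd.DataFrame({
        "sample_id": per_image_ids if per_image_ids is not None
        else [f"image{i}" for i in range(report.n_images)],
        "ipe_mm": report.ipe_per_image,
    }).to_csv(mc, index=False)
    paths["metrics_csv"] = mc
    finite = [x for x in report.ipe_per_image if np.isfinite(x)]
    if curve_grid_mm is None:
        top = max(finite) if finite else 1.0
        curve_grid_mm = np.linspace(0.0, float(top) * 1.05 + 1e-9, 64)
    curve = cumulative_ipe(report.ipe_per_image, curve_grid_mm)
    cc = out_dir / "cumulative_ipe.csv"
    curve.to_csv(cc, index=False)
    paths["curve_csv"] = cc
    return paths
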