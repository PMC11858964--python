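"""Synthetic spine phantoms and calibrated DRR pair simulation.

This module stands in for CT-derived radiograph datasets: it builds simple
attenuation phantoms — a caudal-to-cranial stack of radio-dense ellipsoidal
vertebral bodies, each with a fainter posterior-process ellipsoid to break
AP/LAT symmetry, embedded in a soft-tissue cylinder — and renders calibrated
AP/LAT digitally reconstructed radiographs (DRRs) by integrating attenuation
along source-to-pixel rays. Every sample carries exact 3D body-centre
landmarks, their 2D projections and the projection matrices, so ground truth
is consistent with the geometry by construction.

Default acquisition geometry: source-detector distance 2000 mm, isocenter
distance 1000 mm, oblique (LAO/RAO) angles drawn uniformly within ±15° about
the nominal AP and LAT orientations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import map_coordinates

from .geometry import (
    CameraGeometry,
    GeometryError,
    ProjectionMatrix,
    build_projection,
    project_points,
)

__all__ = [
    "PhantomConfig",
    "AcquisitionConfig",
    "DatasetConfig",
    "PhantomVolume",
    "BiplanarSample",
    "HeatmapStack2D",
    "make_phantom",
    "render_drr",
    "sample_pose_pair",
    "gt_heatmaps_2d",
    "generate_dataset",
    "load_sample",
]


class ConfigurationError(ValueError):
    """Phantom configuration is geometrically impossible."""


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the ellipsoid-stack phantom.

    Sizes approximate adult lumbar anatomy: vertebral bodies with half-axes
    (15, 12, 10) mm spaced 30–40 mm apart centre-to-centre, a fainter
    posterior ellipsoid per vertebra, and a 60 mm soft-tissue cylinder.
    Attenuation units are arbitrary; only ratios matter for DRR appearance.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_spacing_mm: float = 2.0
    body_half_axes_mm: tuple[float, float, float] = (15.0, 12.0, 10.0)
    process_half_axes_mm: tuple[float, float, float] = (7.0, 9.0, 6.0)
    process_offset_mm: float = 20.0  # posterior (+y) shift of the process
    gap_range_mm: tuple[float, float] = (30.0, 40.0)
    lateral_jitter_mm: float = 5.0  # per-vertebra x/y jitter
    stack_offset_mm: float = 8.0  # whole-stack x/y offset range
    attenuation_body: float = 1.0
    attenuation_process: float = 0.6
    attenuation_tissue: float = 0.1
    tissue_radius_mm: float = 60.0


@dataclass(frozen=True)
class AcquisitionConfig:
    """C-arm parameters shared by both views plus the oblique-angle range."""

    sdd_mm: float = 2000.0
    sad_mm: float = 1000.0
    detector_size_mm: tuple[float, float] = (360.0, 360.0)
    detector_pixels: tuple[int, int] = (256, 256)
    angle_range_deg: float = 15.0


@dataclass(frozen=True)
class DatasetConfig:
    """Dataset layout: phantoms per split and pose pairs per phantom.

    The split is assigned at phantom level so that every sample rendered from
    the same phantom lands in the same subset.
    """

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    phantoms_per_split: tuple[int, int, int] = (10, 2, 3)
    pairs_per_phantom: int = 4
    n_vertebrae: int = 3
    drr_step_mm: float = 1.0
    save_png: bool = True
    save_volumes: bool = False


@dataclass
class PhantomVolume:
    """Attenuation grid with world anchoring and body-centre landmarks.

    ``attenuation`` is indexed ``[ix, iy, iz]`` along world (x, y, z);
    ``origin_mm`` is the world position of the centre of voxel (0, 0, 0);
    ``landmarks_mm`` is (L, 3), ordered caudal to cranial.
    """

    attenuation: np.ndarray
    voxel_spacing_mm: np.ndarray
    origin_mm: np.ndarray
    landmarks_mm: np.ndarray

    @property
    def bounds_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """World (lo, hi) corners of the voxel region."""
        lo = self.origin_mm - self.voxel_spacing_mm / 2
        hi = lo + np.array(self.attenuation.shape) * self.voxel_spacing_mm
        return lo, hi

    def save_nifti(self, path: str | Path) -> None:
        import nibabel as nib

        affine = np.diag([*self.voxel_spacing_mm, 1.0])
        affine[:3, 3] = self.origin_mm
        nib.save(nib.Nifti1Image(self.attenuation.astype(np.float32), affine), str(path))


@dataclass
class BiplanarSample:
    """One calibrated AP/LAT image pair with exact landmark ground truth."""

    image_ap: np.ndarray
    image_lat: np.ndarray
    P_ap: ProjectionMatrix
    P_lat: ProjectionMatrix
    geom_ap: CameraGeometry
    geom_lat: CameraGeometry
    landmarks_3d_mm: np.ndarray
    landmarks_2d_px_ap: np.ndarray
    landmarks_2d_px_lat: np.ndarray
    sample_id: str
    rng_seed: int

    def validate(self, atol_px: float = 1e-6) -> None:
        """Check the reprojection invariant landmark_2d == P(landmark_3d)."""
        for P, lm2d in ((self.P_ap, self.landmarks_2d_px_ap),
                        (self.P_lat, self.landmarks_2d_px_lat)):
            reproj = project_points(P, self.landmarks_3d_mm)
            err = np.abs(reproj - lm2d).max()
            if err > atol_px:
                raise ValueError(f"2D ground truth inconsistent with projection ({err} px)")
        if len(self.landmarks_2d_px_ap) != len(self.landmarks_2d_px_lat):
            raise ValueError("views disagree on landmark count")


@dataclass
class HeatmapStack2D:
    """(H, W, L) Gaussian target heatmaps, peak value 1 at each landmark."""

    values: np.ndarray
    sigma_px: float


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

def make_phantom(n_vertebrae: int, seed: int,
                 config: PhantomConfig | None = None) -> PhantomVolume:
    """Build a deterministic ellipsoid-stack phantom.

    Vertebral bodies are stacked along z at centre-to-centre gaps drawn
    uniformly from ``config.gap_range_mm`` and jittered laterally; landmarks
    are the body centres, ordered caudal (low z) to cranial.
    """
    if n_vertebrae < 1:
        raise ConfigurationError("n_vertebrae must be >= 1")
    cfg = config or PhantomConfig()
    rng = np.random.default_rng(seed)

    gaps = rng.uniform(*cfg.gap_range_mm, size=max(n_vertebrae - 1, 0))
    z = np.concatenate([[0.0], np.cumsum(gaps)])
    z -= z.mean()  # centre the stack on the isocenter plane
    stack_xy = rng.uniform(-cfg.stack_offset_mm, cfg.stack_offset_mm, size=2)
    jitter = rng.uniform(-cfg.lateral_jitter_mm, cfg.lateral_jitter_mm,
                         size=(n_vertebrae, 2))
    centres = np.column_stack([
        stack_xy[0] + jitter[:, 0],
        stack_xy[1] + jitter[:, 1],
        z,
    ])

    shape = np.array(cfg.grid_shape)
    spacing = np.full(3, cfg.voxel_spacing_mm)
    origin = -(shape * spacing) / 2 + spacing / 2
    lo = origin - spacing / 2
    hi = lo + shape * spacing

    half = np.array(cfg.body_half_axes_mm)
    if np.any(centres - half < lo) or np.any(centres + half > hi):
        raise ConfigurationError(
            "vertebra extends beyond the phantom volume; reduce n_vertebrae, "
            "gaps, or jitter, or enlarge the grid"
        )

    ax = origin[0] + spacing[0] * np.arange(shape[0])
    ay = origin[1] + spacing[1] * np.arange(shape[1])
    az = origin[2] + spacing[2] * np.arange(shape[2])
    X = ax[:, None, None]
    Y = ay[None, :, None]
    Z = az[None, None, :]

    vol = np.zeros(tuple(shape), dtype=np.float32)
    tissue = np.broadcast_to((X**2 + Y**2) <= cfg.tissue_radius_mm**2, vol.shape)
    vol[tissue] = cfg.attenuation_tissue

    ph = np.array(cfg.process_half_axes_mm)
    for c in centres:
        pc = c + np.array([0.0, cfg.process_offset_mm, 0.0])
        proc = (((X - pc[0]) / ph[0]) ** 2 + ((Y - pc[1]) / ph[1]) ** 2
                + ((Z - pc[2]) / ph[2]) ** 2) <= 1.0
        vol[proc] = np.maximum(vol[proc], cfg.attenuation_process)
    for c in centres:
        body = (((X - c[0]) / half[0]) ** 2 + ((Y - c[1]) / half[1]) ** 2
                + ((Z - c[2]) / half[2]) ** 2) <= 1.0
        vol[body] = cfg.attenuation_body

    return PhantomVolume(
        attenuation=vol,
        voxel_spacing_mm=spacing,
        origin_mm=origin,
        landmarks_mm=centres,
    )


# ---------------------------------------------------------------------------
# DRR rendering
# ---------------------------------------------------------------------------

def render_drr(vol: PhantomVolume, geom: CameraGeometry, step_mm: float = 1.0,
               normalize: bool = True, chunk_steps: int = 24) -> np.ndarray:
    """Render one DRR by fixed-step ray integration with trilinear sampling.

    For every detector pixel the attenuation is integrated along the
    source-to-pixel ray at spacing ``step_mm`` (should not exceed half the
    smallest voxel spacing); the result is the line integral (denser =
    brighter), min–max normalized to [0, 1] unless ``normalize`` is False.
    """
    lo, hi = vol.bounds_mm
    src = geom.source_position()
    if np.all(src >= lo) and np.all(src <= hi):
        raise GeometryError("X-ray source lies inside the phantom volume")

    n_cols, n_rows = geom.detector_pixels
    su, sv = geom.pixel_spacing_mm
    u_axis, v_axis = geom.detector_axes()
    c_det = geom.detector_center()
    cu = (n_cols - 1) / 2.0
    cv = (n_rows - 1) / 2.0
    uu, vv = np.meshgrid(np.arange(n_cols), np.arange(n_rows))  # (H, W)
    pix = (c_det[None, None, :]
           + (uu - cu)[..., None] * su * u_axis[None, None, :]
           + (vv - cv)[..., None] * sv * v_axis[None, None, :])
    dirs = pix - src
    lengths = np.linalg.norm(dirs, axis=-1, keepdims=True)
    dirs = dirs / lengths

    # slab intersection with the voxel region to bound the sampled t-range
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lo = (lo[None, None, :] - src) / dirs
        t_hi = (hi[None, None, :] - src) / dirs
    t_near = np.nanmax(np.minimum(t_lo, t_hi), axis=-1)
    t_far = np.nanmin(np.maximum(t_lo, t_hi), axis=-1)
    hit = t_far > t_near
    if not np.any(hit):
        img = np.zeros((n_rows, n_cols), dtype=np.float32)
        return img
    # integrate only rays that intersect the volume, each from its own entry
    # point; samples beyond a ray's exit fall outside the grid and read as 0
    hit_flat = hit.ravel()
    dirs_hit = dirs.reshape(-1, 3)[hit_flat].astype(np.float32)
    entry = t_near.ravel()[hit_flat].astype(np.float32)
    span = (t_far - t_near).ravel()[hit_flat]
    n_steps = int(np.ceil(float(span.max()) / step_mm))
    src32 = src.astype(np.float32)
    origin32 = vol.origin_mm.astype(np.float32)
    inv_spacing = (1.0 / vol.voxel_spacing_mm).astype(np.float32)
    acc = np.zeros(len(dirs_hit), dtype=np.float32)
    att = vol.attenuation
    for start in range(0, n_steps, chunk_steps):
        offs = ((np.arange(start, min(start + chunk_steps, n_steps)) + 0.5)
                * step_mm).astype(np.float32)
        ts = entry[None, :] + offs[:, None]  # (S, R)
        pts = src32[None, None, :] + ts[..., None] * dirs_hit[None, :, :]
        idx = (pts - origin32) * inv_spacing
        samples = map_coordinates(
            att, idx.reshape(-1, 3).T, order=1, cval=0.0, prefilter=False,
        )
        acc += samples.reshape(len(offs), -1).sum(axis=0)
    integral = np.zeros(n_rows * n_cols, dtype=np.float32)
    integral[hit_flat] = acc * step_mm
    integral = integral.reshape(n_rows, n_cols)

    if not normalize:
        return integral
    mn, mx = float(integral.min()), float(integral.max())
    if mx - mn < 1e-12:
        return np.zeros_like(integral)
    return ((integral - mn) / (mx - mn)).astype(np.float32)


def sample_pose_pair(seed: int, config: AcquisitionConfig | None = None
                     ) -> tuple[CameraGeometry, CameraGeometry]:
    """Draw an (AP, LAT) geometry pair with independent oblique angles.

    Angles are uniform in ±``config.angle_range_deg`` about the nominal
    views; a zero range yields the exact 0° AP and 90° LAT orientations.
    Deterministic in ``seed``.
    """
    cfg = config or AcquisitionConfig()
    rng = np.random.default_rng(seed)
    a_ap, a_lat = rng.uniform(-cfg.angle_range_deg, cfg.angle_range_deg, size=2)
    common = dict(
        sdd_mm=cfg.sdd_mm,
        sad_mm=cfg.sad_mm,
        detector_size_mm=cfg.detector_size_mm,
        detector_pixels=cfg.detector_pixels,
    )
    return (
        CameraGeometry(view_label="AP", lao_rao_deg=float(a_ap), **common),
        CameraGeometry(view_label="LAT", lao_rao_deg=float(a_lat), **common),
    )


def gt_heatmaps_2d(landmarks_2d: np.ndarray, shape: tuple[int, int],
                   sigma_px: float) -> HeatmapStack2D:
    """Gaussian target heatmaps, one channel per landmark, peak value 1.

    Channel ``l`` holds ``exp(-||p - landmark_l||^2 / (2 sigma^2))`` at pixel
    centres; no unit-mass normalization is applied. Landmarks outside the
    image produce attenuated (but finite) channels.
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    H, W = shape
    lm = np.atleast_2d(np.asarray(landmarks_2d, dtype=float))
    uu = np.arange(W, dtype=np.float64)
    vv = np.arange(H, dtype=np.float64)
    d2 = ((uu[None, None, :] - lm[:, 0, None, None]) ** 2
          + (vv[None, :, None] - lm[:, 1, None, None]) ** 2)  # (L, H, W)
    values = np.exp(-d2 / (2.0 * sigma_px**2)).transpose(1, 2, 0).astype(np.float32)
    return HeatmapStack2D(values=values, sigma_px=float(sigma_px))


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _render_sample(phantom: PhantomVolume, pose_seed: int, sample_id: str,
                   cfg: DatasetConfig) -> BiplanarSample:
    geom_ap, geom_lat = sample_pose_pair(pose_seed, cfg.acquisition)
    P_ap = build_projection(geom_ap)
    P_lat = build_projection(geom_lat)
    img_ap = render_drr(phantom, geom_ap, step_mm=cfg.drr_step_mm)
    img_lat = render_drr(phantom, geom_lat, step_mm=cfg.drr_step_mm)
    lm3d = phantom.landmarks_mm
    return BiplanarSample(
        image_ap=img_ap,
        image_lat=img_lat,
        P_ap=P_ap,
        P_lat=P_lat,
        geom_ap=geom_ap,
        geom_lat=geom_lat,
        landmarks_3d_mm=lm3d,
        landmarks_2d_px_ap=project_points(P_ap, lm3d),
        landmarks_2d_px_lat=project_points(P_lat, lm3d),
        sample_id=sample_id,
        rng_seed=pose_seed,
    )


def _sample_hash(sample: BiplanarSample) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(sample.image_ap).tobytes())
    h.update(np.ascontiguousarray(sample.image_lat).tobytes())
    h.update(np.ascontiguousarray(sample.landmarks_3d_mm).tobytes())
    return h.hexdigest()[:16]


def _write_sample(sample: BiplanarSample, out_dir: Path, cfg: DatasetConfig) -> dict:
    import imageio.v3 as iio

    sid = sample.sample_id
    paths = {}
    for view, img in (("ap", sample.image_ap), ("lat", sample.image_lat)):
        tif = out_dir / f"{sid}_{view}.tif"
        tifffile.imwrite(tif, img.astype(np.float32))
        paths[f"image_{view}"] = tif.name
        if cfg.save_png:
            png = out_dir / f"{sid}_{view}.png"
            iio.imwrite(png, (np.clip(img, 0, 1) * 65535).astype(np.uint16))
    meta = {
        "sample_id": sid,
        "rng_seed": sample.rng_seed,
        "geom_ap": sample.geom_ap.to_dict(),
        "geom_lat": sample.geom_lat.to_dict(),
        "P_ap_mm_to_px": sample.P_ap.p.tolist(),
        "P_lat_mm_to_px": sample.P_lat.p.tolist(),
        "landmarks_3d_mm": sample.landmarks_3d_mm.tolist(),
        "landmarks_2d_px_ap": sample.landmarks_2d_px_ap.tolist(),
        "landmarks_2d_px_lat": sample.landmarks_2d_px_lat.tolist(),
        "files": paths,
    }
    meta_path = out_dir / f"{sid}.json"
    meta_path.write_text(json.dumps(meta, indent=1))
    return {"json": meta_path.name, **paths}


def downscale_sample(sample: BiplanarSample, factor: int) -> BiplanarSample:
    """Average-pool both views by an integer factor, keeping geometry exact.

    Output pixel j covers input pixels [factor*j, factor*(j+1)); in the
    pixel-centre convention its centre sits at input coordinate
    ``factor*j + (factor-1)/2``, so the projection matrices and 2D landmarks
    are remapped by the affine ``u' = (u - (factor-1)/2) / factor`` per axis.
    The reprojection invariant is preserved to floating-point precision.
    """
    if factor == 1:
        return sample
    if any(s % factor for img in (sample.image_ap, sample.image_lat)
           for s in img.shape):
        raise ValueError("image dims must be divisible by the pooling factor")

    def pool(img: np.ndarray) -> np.ndarray:
        H, W = img.shape
        return img.reshape(H // factor, factor, W // factor, factor).mean(axis=(1, 3))

    off = (factor - 1) / 2.0
    S = np.array([[1.0 / factor, 0.0, -off / factor],
                  [0.0, 1.0 / factor, -off / factor],
                  [0.0, 0.0, 1.0]])
    return BiplanarSample(
        image_ap=pool(sample.image_ap).astype(np.float32),
        image_lat=pool(sample.image_lat).astype(np.float32),
        P_ap=ProjectionMatrix(S @ sample.P_ap.p),
        P_lat=ProjectionMatrix(S @ sample.P_lat.p),
        geom_ap=sample.geom_ap,
        geom_lat=sample.geom_lat,
        landmarks_3d_mm=sample.landmarks_3d_mm,
        landmarks_2d_px_ap=(sample.landmarks_2d_px_ap - off) / factor,
        landmarks_2d_px_lat=(sample.landmarks_2d_px_lat - off) / factor,
        sample_id=sample.sample_id,
        rng_seed=sample.rng_seed,
    )


def load_sample(json_path: str | Path) -> BiplanarSample:
    """Reload a written sample (float TIFF images + JSON sidecar)."""
    json_path = Path(json_path)
    meta = json.loads(json_path.read_text())
    d = json_path.parent
    return BiplanarSample(
        image_ap=tifffile.imread(d / meta["files"]["image_ap"]),
        image_lat=tifffile.imread(d / meta["files"]["image_lat"]),
        P_ap=ProjectionMatrix(np.asarray(meta["P_ap_mm_to_px"])),
        P_lat=ProjectionMatrix(np.asarray(meta["P_lat_mm_to_px"])),
        geom_ap=CameraGeometry.from_dict(meta["geom_ap"]),
        geom_lat=CameraGeometry.from_dict(meta["geom_lat"]),
        landmarks_3d_mm=np.asarray(meta["landmarks_3d_mm"]),
        landmarks_2d_px_ap=np.asarray(meta["landmarks_2d_px_ap"]),
        landmarks_2d_px_lat=np.asarray(meta["landmarks_2d_px_lat"]),
        sample_id=meta["sample_id"],
        rng_seed=int(meta["rng_seed"]),
    )


def generate_dataset(out_dir: str | Path, seed: int,
                     config: DatasetConfig | None = None) -> pd.DataFrame:
    """Generate a full phantom DRR dataset with phantom-grouped splits.

    Renders ``pairs_per_phantom`` calibrated AP/LAT pairs for every phantom;
    all samples sharing a phantom are assigned to the same split. Writes the
    images, JSON sidecars, and ``manifest.csv``; returns the manifest as a
    DataFrame (sample_id, phantom_id, split, json, content hash). The whole
    dataset is a pure function of (seed, config).
    """
    cfg = config or DatasetConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    split_names = ("train", "val", "test")
    ss = np.random.SeedSequence([int(seed), 0xD4])
    n_total = sum(cfg.phantoms_per_split)
    phantom_seeds = ss.generate_state(n_total * (cfg.pairs_per_phantom + 1)).astype(np.int64)
    k = 0
    phantom_index = 0
    for split, n_phantoms in zip(split_names, cfg.phantoms_per_split):
        for _ in range(n_phantoms):
            pid = f"phantom{phantom_index:03d}"
            phantom = make_phantom(cfg.n_vertebrae, int(phantom_seeds[k] % 2**31), cfg.phantom)
            k += 1
            if cfg.save_volumes:
                phantom.save_nifti(out_dir / f"{pid}.nii.gz")
            for j in range(cfg.pairs_per_phantom):
                sid = f"{pid}_pose{j:02d}"
                pose_seed = int(phantom_seeds[k] % 2**31)
                k += 1
                sample = _render_sample(phantom, pose_seed, sid, cfg)
                sample.validate()
                files = _write_sample(sample, out_dir, cfg)
                rows.append({
                    "sample_id": sid,
                    "phantom_id": pid,
                    "split": split,
                    "json": files["json"],
                    "hash": _sample_hash(sample),
                })
            phantom_index += 1

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    (out_dir / "dataset.json").write_text(json.dumps({
        "seed": int(seed),
        "config": _config_to_jsonable(cfg),
    }, indent=1))
    return manifest


def _config_to_jsonable(cfg) -> dict:
    d = dataclasses.asdict(cfg)

    def conv(x):
        if isinstance(x, dict):
            return {k: conv(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [conv(v) for v in x]
        if isinstance(x, (np.integer, np.floating)):
            return x.item()
        return x

    return conv(d)
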