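"""End-to-end training of the biplanar localization pipeline.

The trained object couples the shared 2D extractor and the 3D regression net
through the projective fusion step: images -> per-view features and fusion
weights -> unprojection into the world-anchored cube -> weighted aggregation
-> 3D SCN -> volumetric softmax -> soft-argmax world coordinates. The whole
chain is differentiable, so the 2D heatmap losses and the 3D coordinate
losses train both nets jointly with Adam (learning rate 1e-3, batch size 4
by default).

Two presets are provided: the desk preset (256x256 rendered images pooled
2x before the nets with exactly remapped projection matrices, 32^3 cube of
side 200 mm, K=8, 80 epochs) sized for CPU-scale experiments on synthetic
phantoms, and a full-scale preset mirroring the hyperparameters a GPU-scale
study would use (K=16, 64^3 cube of side 250 mm, hundreds of epochs).
"""

from __future__ import annotations

import dataclasses
import json
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import nn
from .autodiff import Tensor, concat
from .evaluation import MetricsReport, compute_metrics
from .fusion import VoxelCube, aggregate, make_cube, unproject
from .losses import LossBreakdown, loss_2d, loss_3d
from .phantom import (BiplanarSample, downscale_sample, gt_heatmaps_2d,
                      load_sample)
from .regress3d import (LandmarkPrediction, SCN3D, SCN3DConfig, soft_argmax,
                        volumetric_softmax)
from .scn2d import SCN2D, SCN2DConfig

__all__ = [
    "TrainConfig",
    "TrainResult",
    "TrainingDivergedError",
    "BiplanarLocalizer",
    "desk_config",
    "full_scale_config",
    "train",
    "predict_sample",
    "load_split",
    "save_checkpoint",
    "load_checkpoint",
]


class TrainingDivergedError(RuntimeError):
    """Raised when a loss becomes non-finite; carries the offending batch."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimization and pipeline hyperparameters (recorded verbatim in logs)."""

    lr: float = 1e-3
    batch_size: int = 4
    epochs: int = 50
    seed: int = 0
    sigma_px: float | None = None  # None -> 2% of image height
    cube_side_mm: float = 200.0
    cube_resolution: int = 32
    alpha: float = 0.01
    val_interval: int = 10
    standardize: bool = True
    input_downsample: int = 2  # avg-pool factor applied to images before the net
    scn2d: SCN2DConfig = field(default_factory=SCN2DConfig)
    scn3d: SCN3DConfig = field(default_factory=SCN3DConfig)

    def __post_init__(self) -> None:
        if min(self.lr, self.batch_size, self.epochs) < 0:
            raise ValueError("lr, batch_size and epochs must be nonnegative")
        if self.scn3d.in_channels != self.scn2d.K:
            raise ValueError("3D net input channels must equal the 2D feature count K")

    def resolve_sigma(self, image_height: int) -> float:
        return self.sigma_px if self.sigma_px is not None else 0.02 * image_height

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d))  # tuples -> lists

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        d["scn2d"] = SCN2DConfig(**{**d.get("scn2d", {}),
                                    "enc_channels": tuple(d["scn2d"]["enc_channels"])}) \
            if "scn2d" in d else SCN2DConfig()
        d["scn3d"] = SCN3DConfig(**{**d.get("scn3d", {}),
                                    "enc_channels": tuple(d["scn3d"]["enc_channels"])}) \
            if "scn3d" in d else SCN3DConfig()
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def desk_config(L: int = 3, seed: int = 0, epochs: int = 80) -> TrainConfig:
    """CPU-scale preset: K=8 features, 32^3 cube of side 200 mm, 80 epochs."""
    return TrainConfig(
        seed=seed,
        epochs=epochs,
        val_interval=5,
        scn2d=SCN2DConfig(K=8, L=L),
        scn3d=SCN3DConfig(in_channels=8, L=L),
    )


def full_scale_config(L: int = 5, seed: int = 0, epochs: int = 1500) -> TrainConfig:
    """Full-scale preset (GPU-sized): K=16, 64^3 cube of side 250 mm."""
    return TrainConfig(
        seed=seed,
        epochs=epochs,
        cube_side_mm=250.0,
        cube_resolution=64,
        scn2d=SCN2DConfig(enc_channels=(32, 32, 64, 64, 128), K=16, L=L),
        scn3d=SCN3DConfig(in_channels=16, enc_channels=(16, 32, 32, 64), L=L),
    )


class BiplanarLocalizer(nn.Module):
    """The full pipeline: shared 2D extractor + fusion + 3D regression."""

    def __init__(self, config: TrainConfig, rng: np.random.Generator):
        self.train_config = config
        self.scn2d = SCN2D(config.scn2d, rng)
        self.scn3d = SCN3D(config.scn3d, rng)

    def cube_for(self, sample: BiplanarSample) -> VoxelCube:
        cfg = self.train_config
        return make_cube(
            sample.P_ap, sample.P_lat,
            (sample.image_ap.shape, sample.image_lat.shape),
            side_mm=cfg.cube_side_mm, resolution=cfg.cube_resolution,
        )

    def forward_batch(self, views: Tensor, samples: list[BiplanarSample],
                      cubes: list[VoxelCube]) -> dict:
        """Run N samples; ``views`` stacks (AP_0, LAT_0, AP_1, ...) as (2N,1,H,W)."""
        out2d = self.scn2d.forward(views)
        vols = []
        for i, (sample, cube) in enumerate(zip(samples, cubes)):
            per_view = []
            weights = []
            for j, P in ((2 * i, sample.P_ap), (2 * i + 1, sample.P_lat)):
                per_view.append(unproject(out2d["M"][j], P, cube))
                weights.append(out2d["w"][j])
            vagg = aggregate(per_view, weights)
            D = cube.resolution
            vols.append(vagg.values.reshape((1, -1, D, D, D)))
        v_processed = self.scn3d.forward(concat(vols, axis=0))  # (N, L, D, D, D)
        probs, ys, preds = [], [], []
        for i, (sample, cube) in enumerate(zip(samples, cubes)):
            prob = volumetric_softmax(v_processed[i])
            y, pred = soft_argmax(prob, cube, sample_id=sample.sample_id)
            probs.append(prob)
            ys.append(y)
            preds.append(pred)
        return {"out2d": out2d, "v_processed": v_processed, "v_prob": probs,
                "y": ys, "predictions": preds, "cubes": cubes}


@contextmanager
def frozen_params(model: nn.Module):
    """Temporarily disable gradient tracking for inference passes."""
    params = model.parameters()
    flags = [p.requires_grad for p in params]
    for p in params:
        p.requires_grad = False
    try:
        yield
    finally:
        for p, f in zip(params, flags):
            p.requires_grad = f


def _standardize_image(img: np.ndarray) -> np.ndarray:
    return ((img - img.mean()) / (img.std() + 1e-8)).astype(np.float32)


def _view_stack(samples: list[BiplanarSample], standardize: bool) -> np.ndarray:
    views = []
    for s in samples:
        for img in (s.image_ap, s.image_lat):
            views.append(_standardize_image(img) if standardize else img.astype(np.float32))
    return np.stack(views)[:, None]  # (2N, 1, H, W)


def _target_heatmaps(samples: list[BiplanarSample], sigma_px: float) -> np.ndarray:
    gs = []
    for s in samples:
        for img, lm in ((s.image_ap, s.landmarks_2d_px_ap),
                        (s.image_lat, s.landmarks_2d_px_lat)):
            hm = gt_heatmaps_2d(lm, img.shape, sigma_px).values  # (H, W, L)
            gs.append(np.moveaxis(hm, -1, 0))
    return np.stack(gs).astype(np.float32)  # (2N, L, H, W)


def load_split(data_dir: str | Path, split: str,
               manifest: pd.DataFrame | None = None) -> list[BiplanarSample]:
    """Load every sample of one split from a generated dataset directory."""
    data_dir = Path(data_dir)
    if manifest is None:
        manifest = pd.read_csv(data_dir / "manifest.csv")
    rows = manifest[manifest["split"] == split]
    return [load_sample(data_dir / r.json) for r in rows.itertuples()]


def prepare_sample(config: TrainConfig, sample: BiplanarSample) -> BiplanarSample:
    """Apply the preset's input rescaling (images, P matrices, 2D landmarks)."""
    return downscale_sample(sample, config.input_downsample)


def predict_sample(model: BiplanarLocalizer, sample: BiplanarSample) -> LandmarkPrediction:
    """Inference on one sample (input rescaling applied; no gradient graph)."""
    cfg = model.train_config
    sample = prepare_sample(cfg, sample)
    cube = model.cube_for(sample)
    views = Tensor(_view_stack([sample], cfg.standardize))
    with frozen_params(model):
        out = model.forward_batch(views, [sample], [cube])
    return out["predictions"][0]


@dataclass
class TrainResult:
    model: BiplanarLocalizer
    history: pd.DataFrame
    best_epoch: int
    best_val: MetricsReport | None
    run_dir: Path | None


def train(data_dir: str | Path, config: TrainConfig,
          run_dir: str | Path | None = None,
          samples_train: list[BiplanarSample] | None = None,
          samples_val: list[BiplanarSample] | None = None) -> TrainResult:
    """Minimize the total loss end-to-end on the train split.

    Loads the splits from ``data_dir`` (or accepts preloaded sample lists),
    logs a per-epoch :class:`LossBreakdown` plus periodic validation
    IDrate/PE, and keeps the parameters of the epoch with the best validation
    IDrate (ties broken by lowest PE). Fully deterministic in
    ``config.seed``.
    """
    cfg = config
    if samples_train is None:
        samples_train = load_split(data_dir, "train")
    if samples_val is None:
        try:
            samples_val = load_split(data_dir, "val")
        except Exception:
            samples_val = []
    if not samples_train:
        raise ValueError("empty training split")
    samples_train = [prepare_sample(cfg, s) for s in samples_train]
    samples_val = [prepare_sample(cfg, s) for s in samples_val]

    rng = np.random.default_rng(cfg.seed)
    model = BiplanarLocalizer(cfg, rng)
    opt = nn.Adam(model.parameters(), lr=cfg.lr)

    H = samples_train[0].image_ap.shape[0]
    sigma = cfg.resolve_sigma(H)
    views_all = _view_stack(samples_train, cfg.standardize)
    g_all = _target_heatmaps(samples_train, sigma)
    cubes = [model.cube_for(s) for s in samples_train]
    for s, c in zip(samples_train, cubes):
        if not np.all(c.contains(s.landmarks_3d_mm)):
            raise ValueError(f"sample {s.sample_id}: landmark outside the cube")

    n = len(samples_train)
    history_rows = []
    best = {"idrate": -1.0, "pe": np.inf, "epoch": -1, "state": model.state_dict(),
            "report": None}

    for epoch in range(1, cfg.epochs + 1):
        perm = rng.permutation(n)
        sums = {"l2d_dice": 0.0, "l2d_mse": 0.0, "l3d_l1": 0.0, "l3d_reg": 0.0}
        n_seen = 0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            batch = [samples_train[i] for i in idx]
            bcubes = [cubes[i] for i in idx]
            view_idx = np.stack([2 * idx, 2 * idx + 1], axis=1).ravel()
            x = Tensor(views_all[view_idx])
            out = model.forward_batch(x, batch, bcubes)

            nb = len(batch)
            l_dice, l_mse = loss_2d(out["out2d"]["h"], g_all[view_idx])
            l_dice = l_dice * (1.0 / nb)
            l_mse = l_mse * (1.0 / nb)
            l1_sum, reg_sum = None, None
            for i, s in enumerate(batch):
                l1, reg = loss_3d(out["y"][i], s.landmarks_3d_mm, out["v_prob"][i],
                                  bcubes[i], alpha=cfg.alpha)
                l1_sum = l1 if l1_sum is None else l1_sum + l1
                reg_sum = reg if reg_sum is None else reg_sum + reg
            l1_sum = l1_sum * (1.0 / nb)
            reg_sum = reg_sum * (1.0 / nb)
            total = l_dice + l_mse + l1_sum + reg_sum

            if not np.isfinite(total.data):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch samples "
                    f"{[s.sample_id for s in batch]}"
                )
            opt.zero_grad()
            total.backward()
            opt.step()

            sums["l2d_dice"] += float(l_dice.data) * nb
            sums["l2d_mse"] += float(l_mse.data) * nb
            sums["l3d_l1"] += float(l1_sum.data) * nb
            sums["l3d_reg"] += float(reg_sum.data) * nb
            n_seen += nb

        means = {k: v / n_seen for k, v in sums.items()}
        breakdown = LossBreakdown(
            l2d_dice=means["l2d_dice"], l2d_mse=means["l2d_mse"],
            l3d_l1=means["l3d_l1"], l3d_reg=means["l3d_reg"],
            total=sum(means.values()), alpha=cfg.alpha,
        )
        row = {"epoch": epoch, **means, "total": breakdown.total,
               "val_id_rate_pct": np.nan, "val_pe_mean_mm": np.nan}

        run_val = samples_val and (epoch % cfg.val_interval == 0 or epoch == cfg.epochs)
        if run_val:
            report = _validate(model, samples_val)
            row["val_id_rate_pct"] = report.id_rate_pct
            row["val_pe_mean_mm"] = report.pe_all_mean_mm
            better = (report.id_rate_pct > best["idrate"]
                      or (report.id_rate_pct == best["idrate"]
                          and report.pe_all_mean_mm < best["pe"]))
            if better:
                best.update(idrate=report.id_rate_pct, pe=report.pe_all_mean_mm,
                            epoch=epoch, state=model.state_dict(), report=report)
        history_rows.append(row)

    if best["epoch"] < 0:  # no validation split: keep the final parameters
        best.update(epoch=cfg.epochs, state=model.state_dict())
    model.load_state_dict(best["state"])

    history = pd.DataFrame(history_rows)
    rd = None
    if run_dir is not None:
        rd = Path(run_dir)
        rd.mkdir(parents=True, exist_ok=True)
        save_checkpoint(model, rd)
        cfg.to_yaml(rd / "train_config.yaml")
        history.to_csv(rd / "history.csv", index=False)
        with open(rd / "history.jsonl", "w") as fh:
            for r in history_rows:
                fh.write(json.dumps({k: (None if isinstance(v, float) and np.isnan(v) else v)
                                     for k, v in r.items()}) + "\n")
    return TrainResult(model=model, history=history, best_epoch=best["epoch"],
                       best_val=best["report"], run_dir=rd)


def _validate(model: BiplanarLocalizer, samples: list[BiplanarSample],
              batch_size: int = 4) -> MetricsReport:
    preds, gts = [], []
    cfg = model.train_config
    with frozen_params(model):
        for start in range(0, len(samples), batch_size):
            batch = samples[start:start + batch_size]
            cubes = [model.cube_for(s) for s in batch]
            x = Tensor(_view_stack(batch, cfg.standardize))
            out = model.forward_batch(x, batch, cubes)
            for s, p in zip(batch, out["predictions"]):
                preds.append(p.y_mm)
                gts.append(s.landmarks_3d_mm)
    return compute_metrics(preds, gts)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: BiplanarLocalizer, run_dir: str | Path) -> Path:
    """Write parameters (.npz) plus a JSON architecture fingerprint."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    state = {}
    for prefix, module in (("scn2d", model.scn2d), ("scn3d", model.scn3d)):
        for k, v in module.state_dict().items():
            state[f"{prefix}.{k}"] = v
    path = run_dir / "checkpoint.npz"
    np.savez(path, **state)
    (run_dir / "checkpoint.json").write_text(json.dumps({
        "fingerprints": [model.scn2d.fingerprint(), model.scn3d.fingerprint()],
        "train_config": model.train_config.to_dict(),
    }, indent=1))
    return path


def load_checkpoint(run_dir: str | Path) -> BiplanarLocalizer:
    """Rebuild a model from ``checkpoint.npz`` + ``checkpoint.json``.

    The stored architecture fingerprint is validated against the rebuilt
    modules before parameters are loaded.
    """
    run_dir = Path(run_dir)
    meta = json.loads((run_dir / "checkpoint.json").read_text())
    cfg = TrainConfig.from_dict(meta["train_config"])
    model = BiplanarLocalizer(cfg, np.random.default_rng(0))
    got = [model.scn2d.fingerprint(), model.scn3d.fingerprint()]
    if got != meta["fingerprints"]:
        raise ValueError("checkpoint fingerprint does not match rebuilt architecture")
    data = np.load(run_dir / "checkpoint.npz")
    for prefix, module in (("scn2d", model.scn2d), ("scn3d", model.scn3d)):
        module.load_state_dict({
            k[len(prefix) + 1:]: data[k] for k in data.files if k.startswith(prefix + ".")
        })
    return model
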