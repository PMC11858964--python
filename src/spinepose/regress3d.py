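"""3D landmark regression: 3D SpatialConfiguration-Net, volumetric softmax,
and soft-argmax coordinate readout in world millimetres.

The 3D net mirrors the 2D extractor with volumetric kernels: a U-Net
local-appearance branch whose L-channel head is left linear (unbounded), so
the spatial softmax that follows can sharpen into a peaked distribution, and
a sigmoid-gated spatial-configuration branch that suppresses responses at
look-alike neighbouring vertebrae. The per-channel softmax over all voxels
turns the processed volume into a probability mass, and the soft-argmax is
its centroid in world coordinates — a convex combination of voxel centres,
hence always inside the cube, and differentiable end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .autodiff import Tensor, concat
from .fusion import FeatureVolume, VoxelCube

__all__ = ["SCN3DConfig", "SCN3D", "LandmarkVolume", "LandmarkPrediction",
           "scn3d_forward", "volumetric_softmax", "soft_argmax"]


@dataclass(frozen=True)
class SCN3DConfig:
    """Architecture hyperparameters of the 3D regression net.

    Channel widths are reduced relative to the 2D net: the volume grid is
    small (32^3 by default) and the fused features are already landmark-like.
    """

    in_channels: int = 8  # must equal the 2D feature channel count K
    enc_channels: tuple[int, ...] = (4, 8, 16)
    L: int = 3
    sc_factor: int = 2
    sc_channels: int = 8
    sc_kernel: int = 3
    leaky_slope: float = 0.1


@dataclass
class LandmarkVolume:
    """Pre-softmax 3D SCN output and its per-channel probability mass.

    ``v_processed``/``v_prob`` are (L, D, D, D) tensors; each channel of
    ``v_prob`` is nonnegative and sums to 1.
    """

    v_processed: Tensor
    v_prob: Tensor
    cube: VoxelCube


@dataclass
class LandmarkPrediction:
    """Predicted landmark coordinates (L, 3) in world mm with a confidence
    score per landmark (the peak probability of its channel)."""

    y_mm: np.ndarray
    confidence: np.ndarray
    sample_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_id,
            "landmark_index": np.arange(len(self.y_mm)),
            "x_mm": self.y_mm[:, 0],
            "y_mm": self.y_mm[:, 1],
            "z_mm": self.y_mm[:, 2],
            "confidence": self.confidence,
        })

    def to_slicer_json(self, path: str | Path) -> None:
        """Write a 3D Slicer markups fiducial file for visualization."""
        points = [
            {
                "id": str(i + 1),
                "label": f"V{i + 1}",
                "position": [float(c) for c in p],
                "orientation": [1, 0, 0, 0, 1, 0, 0, 0, 1],
            }
            for i, p in enumerate(self.y_mm)
        ]
        doc = {
            "@schema": "https://raw.githubusercontent.com/Slicer/Slicer/main/Modules/Loadable/Markups/Resources/Schema/markups-schema-v1.0.3.json",
            "markups": [{
                "type": "Fiducial",
                "coordinateSystem": "LPS",
                "controlPoints": points,
            }],
        }
        Path(path).write_text(json.dumps(doc, indent=1))


class _ConvBlock3d(nn.Module):
    """Two 3x3x3 convs (encoder levels)."""

    def __init__(self, in_ch, out_ch, rng, slope):
        self.c1 = nn.Conv3d(in_ch, out_ch, 3, rng)
        self.c2 = nn.Conv3d(out_ch, out_ch, 3, rng)
        self.slope = slope

    def __call__(self, x):
        return self.c2(self.c1(x).leaky_relu(self.slope)).leaky_relu(self.slope)


class _DecBlock3d(nn.Module):
    """Single 3x3x3 conv after skip concatenation (decoder levels)."""

    def __init__(self, in_ch, out_ch, rng, slope):
        self.c1 = nn.Conv3d(in_ch, out_ch, 3, rng)
        self.slope = slope

    def __call__(self, x):
        return self.c1(x).leaky_relu(self.slope)


class SCN3D(nn.Module):
    """3D SCN mapping fused feature volumes to per-landmark volumes."""

    def __init__(self, config: SCN3DConfig, rng: np.random.Generator):
        self.config = config
        ch = config.enc_channels
        s = config.leaky_slope
        self.enc = [_ConvBlock3d(config.in_channels if i == 0 else ch[i - 1], ch[i], rng, s)
                    for i in range(len(ch))]
        self.dec = [_DecBlock3d(ch[i] + ch[i + 1], ch[i], rng, s)
                    for i in range(len(ch) - 1)]
        # linear local-appearance head: unbounded values feed the softmax;
        # small initial scale keeps the initial softmax diffuse so the
        # soft-argmax starts near the cube centre with informative gradients
        self.la_head = nn.Conv3d(ch[0], config.L, 1, rng, weight_scale=0.1)
        self.sc_convs = [
            nn.Conv3d(config.L, config.sc_channels, config.sc_kernel, rng),
            nn.Conv3d(config.sc_channels, config.sc_channels, config.sc_kernel, rng),
            nn.Conv3d(config.sc_channels, config.L, config.sc_kernel, rng),
        ]
        self.slope = s

    def forward(self, v: Tensor) -> Tensor:
        """(N, K, D, D, D) fused features -> (N, L, D, D, D) processed volume."""
        cfg = self.config
        N, K, *sp = v.shape
        div = 2 ** (len(cfg.enc_channels) - 1) * cfg.sc_factor
        if any(s % div for s in sp):
            raise ValueError(f"volume dims {sp} must be divisible by {div}")

        skips = []
        cur = v
        for i, block in enumerate(self.enc):
            cur = block(cur)
            if i < len(self.enc) - 1:
                skips.append(cur)
                cur = cur.avg_pool(2)
        for i in reversed(range(len(self.dec))):
            cur = cur.upsample_nearest(2)
            cur = concat([skips[i], cur], axis=1)
            cur = self.dec[i](cur)

        v_la = self.la_head(cur)  # linear, unbounded

        sc = v_la.avg_pool(cfg.sc_factor)
        sc = self.sc_convs[0](sc).leaky_relu(self.slope)
        sc = self.sc_convs[1](sc).leaky_relu(self.slope)
        sc = self.sc_convs[2](sc)
        v_sc = sc.upsample_linear(cfg.sc_factor).sigmoid()
        return v_la * v_sc

    def fingerprint(self) -> dict:
        cfg = self.config
        return {
            "model": "scn3d",
            "in_channels": cfg.in_channels,
            "enc_channels": list(cfg.enc_channels),
            "L": cfg.L,
            "sc_factor": cfg.sc_factor,
            "sc_channels": cfg.sc_channels,
            "sc_kernel": cfg.sc_kernel,
        }


def scn3d_forward(model: SCN3D, vagg: FeatureVolume) -> LandmarkVolume:
    """Run the 3D SCN on one fused volume and attach the softmax mass."""
    v_processed = model.forward(vagg.values.reshape((1,) + vagg.values.shape))
    v_processed = v_processed.reshape(v_processed.shape[1:])
    return LandmarkVolume(
        v_processed=v_processed,
        v_prob=volumetric_softmax(v_processed),
        cube=vagg.cube,
    )


def volumetric_softmax(v_processed: Tensor) -> Tensor:
    """Per-channel softmax over all voxels of an (L, D, D, D) volume.

    Stabilized by max subtraction; invariant to adding a constant per
    channel. Each output channel sums to 1.
    """
    L = v_processed.shape[0]
    sp = v_processed.shape[1:]
    flat = v_processed.reshape(L, int(np.prod(sp)))
    return flat.softmax_lastaxis().reshape((L,) + sp)


def soft_argmax(v_prob: Tensor, cube: VoxelCube, sample_id: str = "") -> tuple[Tensor, LandmarkPrediction]:
    """Centroid readout: expectation of voxel-centre world coordinates.

    Returns the differentiable (L, 3) coordinate tensor together with a
    detached :class:`LandmarkPrediction` carrying per-landmark confidence
    (the channel's peak probability).
    """
    L = v_prob.shape[0]
    D3 = int(np.prod(v_prob.shape[1:]))
    coords = cube.voxel_centers().astype(v_prob.dtype)  # (D^3, 3)
    y = v_prob.reshape(L, D3) @ Tensor(coords)
    conf = v_prob.data.reshape(L, D3).max(axis=1)
    pred = LandmarkPrediction(y_mm=y.data.copy().astype(float), confidence=conf.astype(float),
                              sample_id=sample_id)
    return y, pred
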