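"""Siamese 2D feature extractor: a 2D SpatialConfiguration-Net backbone.

One weight set serves both radiographic views (the Siamese property is
enforced by construction — callers run the same module on both images). The
local-appearance branch is a 5-level U-Net producing a K-channel feature map
``M`` at input resolution; a 1x1 convolution plus sigmoid turns ``M`` into
the local-appearance heatmaps ``h_la``. The spatial-configuration branch
average-pools ``h_la``, applies three wide convolutions and upsamples back,
yielding a gating field ``h_sc``; the predicted heatmap is the elementwise
product ``h = h_la * h_sc``, bounded in [0, 1] by the sigmoid construction
on both factors. A fusion-weight branch maps the globally pooled bottom-level
U-Net features through a dense layer and a softplus to strictly positive
per-channel weights used by the cross-view aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autodiff import Tensor, concat

__all__ = ["SCN2DConfig", "SCN2D", "FeatureMap2D", "Heatmaps2DPredicted",
           "FusionWeights", "detect_2d"]


@dataclass(frozen=True)
class SCN2DConfig:
    """Architecture hyperparameters of the 2D extractor.

    ``enc_channels`` sets the U-Net width per level (5 levels); ``K`` is the
    feature-map channel count consumed by the fusion module; ``L`` the number
    of landmarks. The spatial-configuration branch pools by ``sc_factor`` and
    uses ``sc_kernel``-sized kernels so its receptive field spans neighbouring
    vertebrae at the pooled resolution.
    """

    in_channels: int = 1
    enc_channels: tuple[int, ...] = (8, 16, 16, 32, 32)
    K: int = 8
    L: int = 3
    sc_factor: int = 4
    sc_channels: int = 8
    sc_kernel: int = 7
    leaky_slope: float = 0.1
    weight_eps: float = 1e-4

    @property
    def levels(self) -> int:
        return len(self.enc_channels)


@dataclass
class FeatureMap2D:
    """(H, W, K) local-appearance feature map of one view."""

    values: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.values.shape[-1]


@dataclass
class Heatmaps2DPredicted:
    """Predicted per-landmark heatmaps ``h = h_la * h_sc``, all (H, W, L)."""

    h: np.ndarray
    h_la: np.ndarray
    h_sc: np.ndarray


@dataclass
class FusionWeights:
    """Strictly positive per-channel fusion weights (K,) of one view."""

    w: np.ndarray


class _ConvBlock(nn.Module):
    """Two 3x3 convs (encoder levels)."""

    def __init__(self, in_ch, out_ch, rng, slope, kernel=3):
        self.c1 = nn.Conv2d(in_ch, out_ch, kernel, rng)
        self.c2 = nn.Conv2d(out_ch, out_ch, kernel, rng)
        self.slope = slope

    def __call__(self, x):
        return self.c2(self.c1(x).leaky_relu(self.slope)).leaky_relu(self.slope)


class _DecBlock(nn.Module):
    """Single 3x3 conv after skip concatenation (decoder levels)."""

    def __init__(self, in_ch, out_ch, rng, slope, kernel=3):
        self.c1 = nn.Conv2d(in_ch, out_ch, kernel, rng)
        self.slope = slope

    def __call__(self, x):
        return self.c1(x).leaky_relu(self.slope)


class SCN2D(nn.Module):
    """The shared 2D extractor; see module docstring for the data flow."""

    def __init__(self, config: SCN2DConfig, rng: np.random.Generator):
        self.config = config
        ch = config.enc_channels
        s = config.leaky_slope
        self.enc = [_ConvBlock(config.in_channels if i == 0 else ch[i - 1], ch[i], rng, s)
                    for i in range(len(ch))]
        self.dec = [_DecBlock(ch[i] + ch[i + 1], ch[i], rng, s)
                    for i in range(len(ch) - 1)]
        self.feat_conv = nn.Conv2d(ch[0], config.K, 3, rng)
        # negative bias so the sigmoid heatmaps start near the sparse
        # foreground prior instead of 0.5 everywhere
        self.la_head = nn.Conv2d(config.K, config.L, 1, rng)
        self.la_head.bias.data[:] = -2.0
        self.sc_convs = [
            nn.Conv2d(config.L, config.sc_channels, config.sc_kernel, rng),
            nn.Conv2d(config.sc_channels, config.sc_channels, config.sc_kernel, rng),
            nn.Conv2d(config.sc_channels, config.L, config.sc_kernel, rng),
        ]
        self.fusion_fc = nn.Linear(ch[-1], config.K, rng)
        self.slope = s

    # -- forward ---------------------------------------------------------
    def forward(self, x: Tensor) -> dict[str, Tensor]:
        """Run a batch (N, 1, H, W); H and W must be divisible by 2^4.

        Returns tensors ``M`` (N,K,H,W), ``h_la``/``h_sc``/``h`` (N,L,H,W)
        and ``w`` (N,K).
        """
        cfg = self.config
        N, C, H, W = x.shape
        div = 2 ** (cfg.levels - 1)
        if H % div or W % div or H % cfg.sc_factor or W % cfg.sc_factor:
            raise ValueError(
                f"image dims must be divisible by {div} and by the "
                f"spatial-configuration pool factor {cfg.sc_factor}, got {H}x{W}"
            )

        skips = []
        cur = x
        for i, block in enumerate(self.enc):
            cur = block(cur)
            if i < len(self.enc) - 1:
                skips.append(cur)
                cur = cur.avg_pool(2)
        bottom = cur  # (N, ch[-1], H/16, W/16)
        for i in reversed(range(len(self.dec))):
            cur = cur.upsample_nearest(2)
            cur = concat([skips[i], cur], axis=1)
            cur = self.dec[i](cur)

        M = self.feat_conv(cur).leaky_relu(self.slope)
        h_la = self.la_head(M).sigmoid()

        sc = h_la.avg_pool(cfg.sc_factor)
        sc = self.sc_convs[0](sc).leaky_relu(self.slope)
        sc = self.sc_convs[1](sc).leaky_relu(self.slope)
        sc = self.sc_convs[2](sc)
        h_sc = sc.upsample_linear(cfg.sc_factor).sigmoid()
        h = h_la * h_sc

        pooled = bottom.mean(axis=(2, 3))  # (N, ch[-1])
        w = self.fusion_fc(pooled).softplus() + cfg.weight_eps
        return {"M": M, "h_la": h_la, "h_sc": h_sc, "h": h, "w": w}

    def extract(self, image: np.ndarray
                ) -> tuple[FeatureMap2D, Heatmaps2DPredicted, FusionWeights]:
        """Single-image convenience wrapper around :meth:`forward`."""
        x = Tensor(np.asarray(image, dtype=np.float32)[None, None])
        out = self.forward(x)
        hwl = lambda t: np.moveaxis(t.data[0], 0, -1)
        return (
            FeatureMap2D(values=hwl(out["M"])),
            Heatmaps2DPredicted(h=hwl(out["h"]), h_la=hwl(out["h_la"]),
                                h_sc=hwl(out["h_sc"])),
            FusionWeights(w=out["w"].data[0].copy()),
        )

    # -- checkpointing ---------------------------------------------------
    def fingerprint(self) -> dict:
        cfg = self.config
        return {
            "model": "scn2d",
            "enc_channels": list(cfg.enc_channels),
            "K": cfg.K,
            "L": cfg.L,
            "sc_factor": cfg.sc_factor,
            "sc_channels": cfg.sc_channels,
            "sc_kernel": cfg.sc_kernel,
        }


def detect_2d(h: Heatmaps2DPredicted | np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel argmax readout of 2D landmark coordinates.

    Accepts an (H, W, L) heatmap array (or the prediction wrapper) and
    returns ``(coords, detected)`` where ``coords`` is (L, 2) in (u, v) and
    ``detected`` flags channels with any nonzero response. Ties resolve to
    the lowest (row, col) in lexicographic order (first maximum in row-major
    scan); undetected channels carry NaN coordinates.
    """
    arr = h.h if isinstance(h, Heatmaps2DPredicted) else np.asarray(h)
    H, W, L = arr.shape
    coords = np.full((L, 2), np.nan)
    detected = np.zeros(L, dtype=bool)
    for l in range(L):
        ch = arr[:, :, l]
        if not np.any(ch > 0):
            continue
        flat = int(np.argmax(ch))
        r, c = divmod(flat, W)
        coords[l] = (c, r)
        detected[l] = True
    return coords, detected
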