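"""Training objective: per-view heatmap losses plus 3D coordinate losses.

The total loss is the plain sum of four terms:

* a Dice loss between predicted and target Gaussian heatmaps, per view
  (mean over channels, summed over the two views) — counters the extreme
  foreground/background imbalance of landmark heatmaps;
* an MSE loss between the same heatmaps, summed over views;
* an L1 loss on the soft-argmax world coordinates (mm);
* a heatmap regularizer ``-alpha * log V'(y_gt)`` that maximizes the
  softmax-normalized volume value at each ground-truth landmark, ensuring a
  peak exists there (``alpha`` defaults to 0.01). The volume is sampled at
  the ground-truth point by trilinear interpolation and floored at 1e-12
  before the log.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, sample_at_points
from .fusion import VoxelCube

__all__ = ["LossBreakdown", "loss_2d", "loss_3d", "DICE_SMOOTH"]

DICE_SMOOTH = 1e-5
LOG_FLOOR = 1e-12


@dataclass
class LossBreakdown:
    """Scalar loss components; ``total`` is their exact sum."""

    l2d_dice: float
    l2d_mse: float
    l3d_l1: float
    l3d_reg: float
    total: float
    alpha: float = 0.01

    def __post_init__(self) -> None:
        expected = self.l2d_dice + self.l2d_mse + self.l3d_l1 + self.l3d_reg
        if not np.isclose(self.total, expected, rtol=1e-6, atol=1e-9):
            raise ValueError("total must equal the sum of the four components")


def loss_2d(h: Tensor, g: np.ndarray | Tensor,
            smooth: float = DICE_SMOOTH) -> tuple[Tensor, Tensor]:
    """Dice and MSE heatmap losses over a stack of views.

    ``h`` and ``g`` are (V, L, H, W) — predicted heatmaps in [0, 1] and
    Gaussian targets, with the view axis first. The Dice term is
    ``1 - (2 sum(hg) + s) / (sum(h^2) + sum(g^2) + s)`` per channel, averaged
    over channels and summed over views; the MSE term is the per-view mean
    squared difference, summed over views.
    """
    g = g if isinstance(g, Tensor) else Tensor(np.asarray(g, dtype=h.dtype))
    if h.shape != g.shape:
        raise ValueError(f"shape mismatch: {h.shape} vs {g.shape}")
    V = h.shape[0]
    inter = (h * g).sum(axis=(2, 3))            # (V, L)
    denom = (h**2).sum(axis=(2, 3)) + (g**2).sum(axis=(2, 3))
    dice = 1.0 - (2.0 * inter + smooth) / (denom + smooth)
    l_dice = dice.mean(axis=1).sum()            # mean channels, sum views
    l_mse = ((h - g) ** 2).mean(axis=(1, 2, 3)).sum()
    return l_dice, l_mse


def loss_3d(y: Tensor, y_gt: np.ndarray, v_prob: Tensor, cube: VoxelCube,
            alpha: float = 0.01) -> tuple[Tensor, Tensor]:
    """L1 coordinate loss (mm) and the log-probability regularizer.

    ``y`` is the (L, 3) soft-argmax output, ``y_gt`` the ground truth in
    world mm (must lie inside the cube), ``v_prob`` the (L, D, D, D)
    softmax-normalized volume.
    """
    y_gt = np.asarray(y_gt, dtype=float)
    if y_gt.shape != tuple(y.shape):
        raise ValueError(f"ground truth shape {y_gt.shape} != prediction {tuple(y.shape)}")
    if not np.all(cube.contains(y_gt)):
        raise ValueError("ground-truth landmark outside the voxel cube")
    l1 = (y - Tensor(y_gt.astype(y.dtype))).abs().sum()
    v_eval = sample_at_points(v_prob, cube.world_to_index(y_gt))
    reg = -alpha * v_eval.clip_min(LOG_FLOOR).log().sum()
    return l1, reg
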