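"""Spatial alignment fusion: world-anchored voxel cube, feature unprojection,
and learned cross-view aggregation.

The cube is axis-aligned with the world frame, its centre triangulated from
the two image-centre pixels. Unprojection fills each voxel with the bilinear
sample of a 2D feature map at the voxel centre's projected pixel location
(zero outside the image), so the operation is linear and differentiable in
the features. Per-channel aggregation is a weighted average of the per-view
volumes with strictly positive learned weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, grid_sample2d
from .geometry import ProjectionMatrix, project_points, triangulate

__all__ = ["VoxelCube", "FeatureVolume", "make_cube", "unproject", "aggregate"]


@dataclass(frozen=True)
class VoxelCube:
    """A cubical world region sampled at ``resolution^3`` voxel centres.

    Voxel centres span ``center ± (side - voxel)/2`` per axis (voxel-centre
    convention); ``voxel_size_mm = side_mm / resolution``.
    """

    center_mm: tuple[float, float, float]
    side_mm: float = 250.0
    resolution: int = 64

    def __post_init__(self) -> None:
        if self.resolution < 2:
            raise ValueError("cube resolution must be >= 2")
        if self.side_mm <= 0:
            raise ValueError("cube side must be positive")

    @property
    def voxel_size_mm(self) -> float:
        return self.side_mm / self.resolution

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis (mm)."""
        D = self.resolution
        return (np.asarray(self.center_mm)[axis]
                + (np.arange(D) - (D - 1) / 2.0) * self.voxel_size_mm)

    def voxel_centers(self) -> np.ndarray:
        """(D^3, 3) world coordinates of all voxel centres, index order
        (x, y, z) with z fastest."""
        xs = [self.axis_coords(a) for a in range(3)]
        g = np.stack(np.meshgrid(*xs, indexing="ij"), axis=-1)
        return g.reshape(-1, 3)

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points_mm)
        lo = np.asarray(self.center_mm) - self.side_mm / 2
        hi = np.asarray(self.center_mm) + self.side_mm / 2
        return np.all((p >= lo) & (p <= hi), axis=1)

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Fractional voxel-index coordinates of world points."""
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        D = self.resolution
        return (p - np.asarray(self.center_mm)) / self.voxel_size_mm + (D - 1) / 2.0


@dataclass
class FeatureVolume:
    """A (K, D, D, D) feature tensor anchored to a :class:`VoxelCube`.

    The channel-first layout matches the network layers; axis order after the
    channel axis is (x, y, z) in the world frame.
    """

    values: Tensor
    cube: VoxelCube

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def to_numpy(self) -> np.ndarray:
        """(D, D, D, K) array view for inspection/export."""
        return np.moveaxis(self.values.data, 0, -1)

    def save_nifti(self, path, channel: int) -> None:
        """Export one channel as NIfTI for visual inspection."""
        import nibabel as nib

        cube = self.cube
        vox = cube.voxel_size_mm
        affine = np.diag([vox, vox, vox, 1.0])
        affine[:3, 3] = [cube.axis_coords(a)[0] for a in range(3)]
        nib.save(nib.Nifti1Image(self.values.data[channel].astype(np.float32), affine), str(path))


def make_cube(P_ap: ProjectionMatrix, P_lat: ProjectionMatrix,
              image_shapes: tuple[tuple[int, int], tuple[int, int]],
              side_mm: float = 250.0, resolution: int = 64) -> VoxelCube:
    """Anchor the cube at the triangulation of the two image-centre pixels.

    ``image_shapes`` holds the (H, W) of the AP and LAT images; the centre
    pixel of view ``(H, W)`` is ``((W-1)/2, (H-1)/2)`` in (u, v).
    """
    obs = []
    for P, (H, W) in zip((P_ap, P_lat), image_shapes):
        obs.append((P, ((W - 1) / 2.0, (H - 1) / 2.0)))
    center = triangulate(obs)
    return VoxelCube(center_mm=tuple(center), side_mm=side_mm, resolution=resolution)


def unproject(M: Tensor, P: ProjectionMatrix, cube: VoxelCube) -> FeatureVolume:
    """Unproject a (K, H, W) 2D feature map into the cube.

    Every voxel centre is projected through ``P``; the voxel takes the
    bilinear sample of each feature channel at that pixel (zero when the
    projection falls outside the image). Gradients flow to ``M`` through the
    bilinear weights; the projection itself is a fixed linear map.
    """
    K = M.shape[0]
    D = cube.resolution
    uv = project_points(P, cube.voxel_centers())
    sampled = grid_sample2d(M, uv)  # (D^3, K)
    vol = sampled.transpose(1, 0).reshape(K, D, D, D)
    return FeatureVolume(values=vol, cube=cube)


def aggregate(volumes: list[FeatureVolume], weights: list[Tensor],
              eps: float = 1e-8) -> FeatureVolume:
    """Channelwise weighted average of per-view volumes.

    ``Vagg[k] = sum_i w_i[k] V_i[k] / sum_i w_i[k]``; weights must be
    strictly positive (K,) tensors, one per view. ``eps`` guards the
    denominator defensively.
    """
    if len(volumes) != len(weights) or len(volumes) < 1:
        raise ValueError("need one weight vector per volume")
    cube = volumes[0].cube
    K = volumes[0].n_channels
    for v in volumes[1:]:
        if v.cube != cube or v.n_channels != K:
            raise ValueError("volumes must share cube and channel count")
    for w in weights:
        if w.shape != (K,):
            raise ValueError(f"weights must have shape ({K},)")
        if np.any(w.data <= 0):
            raise ValueError("fusion weights must be strictly positive")

    num = None
    den = None
    for v, w in zip(volumes, weights):
        wk = w.reshape(K, 1, 1, 1)
        term = v.values * wk
        num = term if num is None else num + term
        den = wk if den is None else den + wk
    agg = num / (den + eps)
    return FeatureVolume(values=agg, cube=cube)
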