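"""Calibrated projection geometry for biplanar radiographic views.

The acquisition is modelled as an ideal C-arm: a point source at distance
``sad_mm`` from the isocenter, a flat detector at distance ``sdd_mm`` from the
source, and a signed oblique (LAO/RAO) rotation of the whole source–detector
assembly about the patient's cranio-caudal axis.

World frame convention (fixed throughout the package):

* origin at the isocenter, coordinates in millimetres;
* ``z`` is cranio-caudal, superior positive;
* the AP view ray points along ``+y`` at 0° obliquity (source on the
  anterior, ``-y``, side), and the LAT view is the AP assembly rotated
  +90° about ``z``;
* positive LAO angle rotates the assembly further counter-clockwise about
  ``z`` when seen from superior.

Pixel convention: 0-based, coordinates at pixel centres, ``(u, v)`` =
(column, row); detector rows increase caudally (the detector ``v`` axis is
anti-parallel to world ``z``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CameraGeometry",
    "ProjectionMatrix",
    "GeometryError",
    "DegenerateProjectionError",
    "DegenerateGeometryError",
    "build_projection",
    "project_point",
    "project_points",
    "triangulate",
]

#: base assembly rotation (degrees about world z) of each nominal view
VIEW_BASE_ANGLE_DEG = {"AP": 0.0, "LAT": 90.0}


class GeometryError(ValueError):
    """Invalid physical acquisition parameters."""


class DegenerateProjectionError(ArithmeticError):
    """Point projects with a vanishing homogeneous scale (on the source plane)."""


class DegenerateGeometryError(ArithmeticError):
    """Triangulation system is rank deficient (identical or near-parallel views)."""


@dataclass(frozen=True)
class CameraGeometry:
    """Physical acquisition parameters of a single radiographic view.

    Parameters
    ----------
    view_label:
        ``"AP"`` or ``"LAT"``; selects the nominal assembly orientation.
    sdd_mm:
        Source-to-detector distance in mm.
    sad_mm:
        Source-to-isocenter (axis) distance in mm; must satisfy
        ``sdd_mm > sad_mm > 0``.
    lao_rao_deg:
        Signed oblique rotation (degrees) about the cranio-caudal axis,
        relative to the nominal view.
    detector_size_mm:
        Physical detector (width, height) in mm.
    detector_pixels:
        Detector grid as (n_cols, n_rows).
    """

    view_label: str
    sdd_mm: float
    sad_mm: float
    lao_rao_deg: float
    detector_size_mm: tuple[float, float]
    detector_pixels: tuple[int, int]

    def __post_init__(self) -> None:
        if self.view_label not in VIEW_BASE_ANGLE_DEG:
            raise GeometryError(f"view_label must be AP or LAT, got {self.view_label!r}")
        vals = [self.sdd_mm, self.sad_mm, self.lao_rao_deg, *self.detector_size_mm]
        if not all(np.isfinite(v) for v in vals):
            raise GeometryError("non-finite geometry parameter")
        if not (self.sdd_mm > self.sad_mm > 0):
            raise GeometryError(
                f"require sdd_mm > sad_mm > 0, got sdd={self.sdd_mm}, sad={self.sad_mm}"
            )
        if not all(s > 0 for s in self.detector_size_mm):
            raise GeometryError("detector_size_mm must be positive")
        if not all(isinstance(n, (int, np.integer)) and n > 0 for n in self.detector_pixels):
            raise GeometryError("detector_pixels must be positive integers")

    @property
    def pixel_spacing_mm(self) -> tuple[float, float]:
        """(width, height) of one pixel in mm."""
        return (
            self.detector_size_mm[0] / self.detector_pixels[0],
            self.detector_size_mm[1] / self.detector_pixels[1],
        )

    @property
    def assembly_angle_deg(self) -> float:
        """Total rotation about world z: nominal view base + oblique angle."""
        return VIEW_BASE_ANGLE_DEG[self.view_label] + self.lao_rao_deg

    @property
    def image_shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) — numpy image shape of this view."""
        return (self.detector_pixels[1], self.detector_pixels[0])

    # -- frame vectors ---------------------------------------------------
    def view_direction(self) -> np.ndarray:
        """Unit ray direction from source towards detector (world frame)."""
        th = np.deg2rad(self.assembly_angle_deg)
        return np.array([-np.sin(th), np.cos(th), 0.0])

    def detector_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit (u, v) detector axes in world coordinates."""
        th = np.deg2rad(self.assembly_angle_deg)
        u_axis = np.array([np.cos(th), np.sin(th), 0.0])
        v_axis = np.array([0.0, 0.0, -1.0])  # rows increase caudally
        return u_axis, v_axis

    def source_position(self) -> np.ndarray:
        """World position of the X-ray point source (mm)."""
        return -self.sad_mm * self.view_direction()

    def detector_center(self) -> np.ndarray:
        """World position of the detector-plane centre (mm)."""
        return self.source_position() + self.sdd_mm * self.view_direction()

    def to_dict(self) -> dict:
        return {
            "view": self.view_label,
            "sdd_mm": self.sdd_mm,
            "sad_mm": self.sad_mm,
            "lao_rao_deg": self.lao_rao_deg,
            "detector_size_mm": list(self.detector_size_mm),
            "detector_pixels": list(self.detector_pixels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraGeometry":
        return cls(
            view_label=d["view"],
            sdd_mm=float(d["sdd_mm"]),
            sad_mm=float(d["sad_mm"]),
            lao_rao_deg=float(d["lao_rao_deg"]),
            detector_size_mm=tuple(float(x) for x in d["detector_size_mm"]),
            detector_pixels=tuple(int(x) for x in d["detector_pixels"]),
        )


@dataclass(frozen=True)
class ProjectionMatrix:
    """3x4 homogeneous mapping world mm -> pixel coordinates (u, v)."""

    p: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (3, 4):
            raise GeometryError(f"projection matrix must be 3x4, got {p.shape}")
        if not np.all(np.isfinite(p)):
            raise GeometryError("projection matrix has non-finite entries")
        if np.linalg.matrix_rank(p) != 3:
            raise GeometryError("projection matrix must have rank 3")
        object.__setattr__(self, "p", p)

    def to_dict(self) -> dict:
        return {"P": self.p.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectionMatrix":
        return cls(np.asarray(d["P"], dtype=float))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def build_projection(geom: CameraGeometry) -> ProjectionMatrix:
    """Assemble ``P = K [R | t]`` for one calibrated view.

    Intrinsics use the pinhole model: focal lengths ``sdd_mm`` divided by the
    per-axis pixel spacing, principal point at the detector centre in the
    0-based pixel-centre convention ``((n_cols-1)/2, (n_rows-1)/2)``.
    Extrinsics place the source at ``sad_mm`` from the isocenter along the
    view direction (see module docstring for the frame convention).
    """
    su, sv = geom.pixel_spacing_mm
    n_cols, n_rows = geom.detector_pixels
    fu = geom.sdd_mm / su
    fv = geom.sdd_mm / sv
    cx = (n_cols - 1) / 2.0
    cy = (n_rows - 1) / 2.0
    K = np.array([[fu, 0.0, cx], [0.0, fv, cy], [0.0, 0.0, 1.0]])

    u_axis, v_axis = geom.detector_axes()
    d = geom.view_direction()
    R = np.stack([u_axis, v_axis, d])  # world -> camera
    t = -R @ geom.source_position()
    P = K @ np.hstack([R, t[:, None]])
    return ProjectionMatrix(P)


def project_points(P: ProjectionMatrix | np.ndarray, x: np.ndarray) -> np.ndarray:
    """Project one or many 3D world points (mm) to pixel (u, v).

    ``x`` is (3,) or (N, 3); returns the matching (2,) or (N, 2). Points may
    project outside the detector bounds — no clipping is applied.

    Raises
    ------
    DegenerateProjectionError
        If any homogeneous scale ``|w|`` falls below 1e-12.
    """
    p = P.p if isinstance(P, ProjectionMatrix) else np.asarray(P, dtype=float)
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    pts = np.atleast_2d(x)
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite 3D point")
    hom = p @ np.hstack([pts, np.ones((len(pts), 1))]).T  # (3, N)
    w = hom[2]
    if np.any(np.abs(w) < 1e-12):
        raise DegenerateProjectionError("point projects with |w| < 1e-12")
    uv = (hom[:2] / w).T
    return uv[0] if single else uv


def project_point(P: ProjectionMatrix | np.ndarray, x: Sequence[float]) -> np.ndarray:
    """Project a single 3D point; see :func:`project_points`."""
    return project_points(P, np.asarray(x, dtype=float))


def triangulate(
    obs: Sequence[tuple[ProjectionMatrix | np.ndarray, Sequence[float]]],
    cond_threshold: float = 1e-8,
) -> np.ndarray:
    """Linear algebraic (DLT) triangulation of a 3D point from >= 2 views.

    Each observation ``(P, (u, v))`` contributes the two homogeneous rows
    ``u p3^T - p1^T`` and ``v p3^T - p2^T``; the stacked system is solved by
    SVD and the minimizer of the algebraic error is dehomogenized. No Hartley
    normalization is applied: pixel coordinates at detector scale are
    well-conditioned for SVD.

    Raises
    ------
    DegenerateGeometryError
        If the second-smallest singular value falls below
        ``cond_threshold`` times the largest (identical or near-parallel
        views leave the null space ambiguous).
    """
    if len(obs) < 2:
        raise ValueError("triangulation needs at least two observations")
    rows = []
    for P, uv in obs:
        p = P.p if isinstance(P, ProjectionMatrix) else np.asarray(P, dtype=float)
        u, v = float(uv[0]), float(uv[1])
        rows.append(u * p[2] - p[0])
        rows.append(v * p[2] - p[1])
    A = np.asarray(rows)
    _, s, vt = np.linalg.svd(A)
    if s[-2] <= cond_threshold * s[0]:
        raise DegenerateGeometryError(
            "degenerate triangulation geometry (identical or near-parallel views)"
        )
    X = vt[-1]
    if abs(X[3]) < 1e-14:
        raise DegenerateGeometryError("triangulated point at infinity")
    return X[:3] / X[3]
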