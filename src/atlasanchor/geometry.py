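"""Anchoring vectors and pixel/voxel plane geometry.

A 2D section image is placed inside a 3D atlas by three vectors expressed
in atlas voxels: ``o`` points from the atlas origin to the top-left corner
of the matching atlas slice, ``u`` spans its horizontal edge (top-left to
top-right) and ``v`` its vertical edge (top-left to bottom-left).  Pixel
``(x, y)`` of a ``w``-by-``h`` image then maps to the continuous voxel
coordinate ``o + (x/w)*u + (y/h)*v``; the four image corners land on
``o``, ``o+u``, ``o+v`` and ``o+u+v``.

The voxel frame is RAS: x grows left-to-right, y posterior-to-anterior,
z inferior-to-superior, with the origin at the bottom-left corner of the
most anterior coronal plane.  All geometry is double precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "Anchoring",
    "Pose",
    "ImageDims",
    "DegenerateAnchoringError",
    "pixel_to_voxel",
    "voxel_to_pixel",
    "anchoring_matrix",
    "pose_to_anchoring",
    "anchoring_to_pose",
]


class DegenerateAnchoringError(ValueError):
    """Raised when an operation needs a proper plane but ``|u x v| == 0``."""


def _vec3(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {arr}")
    return arr


@dataclass(frozen=True, eq=False)
class Anchoring:
    """Placement of one section plane in atlas-voxel space.

    Parameters
    ----------
    o : array-like of 3 floats
        Top-left corner of the atlas slice, in voxels.
    u : array-like of 3 floats
        Horizontal edge vector (top-left to top-right), in voxels.
    v : array-like of 3 floats
        Vertical edge vector (top-left to bottom-left), in voxels.
    """

    o: np.ndarray
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "o", _vec3(self.o, "o"))
        object.__setattr__(self, "u", _vec3(self.u, "u"))
        object.__setattr__(self, "v", _vec3(self.v, "v"))

    @property
    def normal(self) -> np.ndarray:
        """Unit plane normal ``(u x v) / |u x v|``."""
        n = np.cross(self.u, self.v)
        norm = float(np.linalg.norm(n))
        if norm == 0.0:
            raise DegenerateAnchoringError(
                "anchoring is degenerate: u and v are collinear (|u x v| = 0)"
            )
        return n / norm

    def is_degenerate(self) -> bool:
        return float(np.linalg.norm(np.cross(self.u, self.v))) == 0.0

    def as_flat(self) -> list[float]:
        """The 9 components in ox..oz, ux..uz, vx..vz order."""
        return [*self.o.tolist(), *self.u.tolist(), *self.v.tolist()]

    @classmethod
    def from_flat(cls, values) -> "Anchoring":
        values = list(values)
        if len(values) != 9:
            raise ValueError(f"anchoring needs 9 components, got {len(values)}")
        return cls(values[0:3], values[3:6], values[6:9])

    def __eq__(self, other) -> bool:
        if not isinstance(other, Anchoring):
            return NotImplemented
        return self.as_flat() == other.as_flat()

    def __hash__(self) -> int:
        return hash(tuple(self.as_flat()))

    def allclose(self, other: "Anchoring", atol: float = 0.0) -> bool:
        return (
            np.allclose(self.o, other.o, rtol=0, atol=atol)
            and np.allclose(self.u, other.u, rtol=0, atol=atol)
            and np.allclose(self.v, other.v, rtol=0, atol=atol)
        )


class ImageDims(NamedTuple):
    """Pixel dimensions of the (full-resolution) section image."""

    w: int
    h: int


@dataclass(frozen=True)
class Pose:
    """Human-oriented plane parameterization: position, tilt and scale.

    ``center`` is the plane midpoint in voxels.  ``dv_angle`` (degrees)
    tilts the plane about its image-horizontal axis; positive values move
    the top of the image anterior.  ``ml_angle`` tilts about the
    image-vertical axis; positive values move the image-right edge
    anterior.  ``width_scale``/``height_scale`` multiply the default
    full-extent plane edges.
    """

    center: np.ndarray
    dv_angle: float = 0.0
    ml_angle: float = 0.0
    width_scale: float = 1.0
    height_scale: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", _vec3(self.center, "center"))
        for name in ("dv_angle", "ml_angle"):
            a = float(getattr(self, name))
            if not -90.0 < a < 90.0:
                raise ValueError(f"{name} must lie in (-90, 90) degrees, got {a}")
        for name in ("width_scale", "height_scale"):
            s = float(getattr(self, name))
            if not s > 0:
                raise ValueError(f"{name} must be positive, got {s}")


def pixel_to_voxel(a: Anchoring, x: float, y: float, dims: ImageDims) -> np.ndarray:
    """Map image pixel ``(x, y)`` to continuous atlas-voxel coordinates.

    Returns ``o + (x/w)*u + (y/h)*v``.  ``x`` and ``y`` may be fractional
    and may lie outside the image (the plane extends beyond the section).
    """
    w, h = dims
    return a.o + (x / w) * a.u + (y / h) * a.v


def voxel_to_pixel(
    a: Anchoring, p, dims: ImageDims
) -> tuple[float, float, float]:
    """Invert :func:`pixel_to_voxel`, tolerating out-of-plane points.

    Decomposes ``p - o = s*u + t*v + d*n`` with ``n = (u x v)/|u x v|``
    and returns ``(s*w, t*h, d)``: the pixel coordinates of the in-plane
    projection plus the signed out-of-plane distance in voxels.
    """
    p = _vec3(p, "p")
    n = a.normal  # raises on degenerate anchoring
    basis = np.column_stack([a.u, a.v, n])
    s, t, d = np.linalg.solve(basis, p - a.o)
    w, h = dims
    return (float(s * w), float(t * h), float(d))


def anchoring_matrix(a: Anchoring, dims: ImageDims | None = None) -> np.ndarray:
    """3x3 matrix M with rows u, v, o, so that ``(x/w, y/h, 1) @ M``
    reproduces :func:`pixel_to_voxel`.  ``dims`` is accepted for symmetry
    with the other operations but does not enter the matrix."""
    return np.vstack([a.u, a.v, a.o])


# -- pose <-> anchoring -----------------------------------------------------
#
# Zero pose (dv=0, ml=0, scales 1) at coronal position y0 on an atlas of
# (Nx, Ny, Nz) voxels is o=(0, y0, Nz), u=(Nx, 0, 0), v=(0, 0, -Nz):
# image left = subject's left, image top = superior (screen y grows down).
# Tilts are intrinsic rotations about the plane's own axes through its
# center: dv about the u direction, then ml about the tilted v direction.


def pose_to_anchoring(pose: Pose, atlas_dims) -> Anchoring:
    """Build the o/u/v anchoring realizing a pose on a given atlas grid."""
    nx, ny, nz = (float(d) for d in atlas_dims)
    dv = math.radians(pose.dv_angle)
    ml = math.radians(pose.ml_angle)
    w = nx * pose.width_scale
    h = nz * pose.height_scale
    cdv, sdv = math.cos(dv), math.sin(dv)
    cml, sml = math.cos(ml), math.sin(ml)
    u = np.array([w * cml, w * sml * cdv, -w * sml * sdv])
    v = np.array([0.0, -h * sdv, -h * cdv])
    o = pose.center - u / 2.0 - v / 2.0
    return Anchoring(o, u, v)


def anchoring_to_pose(a: Anchoring, atlas_dims) -> Pose:
    """Recover the pose of an anchoring expressible in the tilt convention.

    Raises ``ValueError`` for planes tilted 90 degrees or more away from
    the coronal orientation (the convention cannot represent them).
    """
    nx, ny, nz = (float(d) for d in atlas_dims)
    w = float(np.linalg.norm(a.u))
    h = float(np.linalg.norm(a.v))
    if w == 0.0 or h == 0.0:
        raise DegenerateAnchoringError("anchoring has a zero-length edge vector")
    # v = h * (0, -sin dv, -cos dv)
    if -a.v[2] <= 0.0:
        raise ValueError("plane is tilted >= 90 degrees from coronal (v)")
    dv = math.atan2(-a.v[1], -a.v[2])
    cdv, sdv = math.cos(dv), math.sin(dv)
    # u = w * (cos ml, sin ml cos dv, -sin ml sin dv)
    sml_w = a.u[1] * cdv - a.u[2] * sdv  # = w sin ml
    if a.u[0] <= 0.0:
        raise ValueError("plane is tilted >= 90 degrees from coronal (u)")
    ml = math.atan2(sml_w, a.u[0])
    center = a.o + a.u / 2.0 + a.v / 2.0
    return Pose(
        center=center,
        dv_angle=math.degrees(dv),
        ml_angle=math.degrees(ml),
        width_scale=w / nx,
        height_scale=h / nz,
    )
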