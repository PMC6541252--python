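"""Voxel-to-physical affine transforms for published reference spaces.

Two spaces ship built in:

* ``allen_ccfv3`` — the Allen Mouse Brain Common Coordinate Framework v3.
  Physical output is in micrometres with PIR axis order (x grows
  anterior-to-posterior, y superior-to-inferior, z left-to-right).
* ``whs_rat`` — Waxholm Space for the rat brain.  Physical output is in
  millimetres with RAS axis order.

The 4x4 matrices are stored exactly as published (row-vector convention,
``(xv, yv, zv, 1) @ M``) and are never re-derived from resolution
constants; the printed matrix is the ground truth, including the PIR axis
reordering for the Allen space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Anchoring, ImageDims, pixel_to_voxel

__all__ = [
    "AtlasSpace",
    "PhysicalPoint",
    "ALLEN_CCFV3",
    "WHS_RAT",
    "get_space",
    "register_space",
    "voxel_to_physical",
    "physical_to_voxel",
    "pixel_to_physical",
]


@dataclass(frozen=True)
class PhysicalPoint:
    """A physical coordinate triple that carries its axis labels and units,
    so PIR-vs-RAS confusion is structurally impossible."""

    values: tuple[float, float, float]
    axes: str
    units: str

    def __array__(self, dtype=None, copy=None):
        return np.array(self.values, dtype=dtype or float)

    def __getitem__(self, i):
        return self.values[i]

    def __iter__(self):
        return iter(self.values)

    def __len__(self):
        return 3

    def labelled(self) -> dict[str, float]:
        return {axis: val for axis, val in zip(self.axes, self.values)}


@dataclass(frozen=True)
class AtlasSpace:
    """A named voxel-to-physical affine (row-vector convention)."""

    name: str
    axis_order_out: str
    units_out: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("space matrix must be 4x4")
        if not np.array_equal(m[:, 3], [0.0, 0.0, 0.0, 1.0]):
            raise ValueError(
                "last matrix column must be (0,0,0,1) under the row-vector convention"
            )
        if np.linalg.det(m) == 0.0:
            raise ValueError("space matrix must be invertible")
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)


ALLEN_CCFV3 = AtlasSpace(
    name="allen_ccfv3",
    axis_order_out="PIR",
    units_out="um",
    matrix=np.array(
        [
            [0.0, 0.0, 25.0, 0.0],
            [-25.0, 0.0, 0.0, 0.0],
            [0.0, -25.0, 0.0, 0.0],
            [13175.0, 7975.0, 0.0, 1.0],
        ]
    ),
)

WHS_RAT = AtlasSpace(
    name="whs_rat",
    axis_order_out="RAS",
    units_out="mm",
    matrix=np.array(
        [
            [0.0390625, 0.0, 0.0, 0.0],
            [0.0, 0.0390625, 0.0, 0.0],
            [0.0, 0.0, 0.0390625, 0.0],
            [-9.53125, -24.3359375, -9.6875, 1.0],
        ]
    ),
)

_REGISTRY: dict[str, AtlasSpace] = {
    "allen_ccfv3": ALLEN_CCFV3,
    "whs_rat": WHS_RAT,
    # short aliases used by the command line
    "allen": ALLEN_CCFV3,
    "whs": WHS_RAT,
}


def get_space(space: "str | AtlasSpace") -> AtlasSpace:
    if isinstance(space, AtlasSpace):
        return space
    try:
        return _REGISTRY[space]
    except KeyError:
        known = sorted(set(s.name for s in _REGISTRY.values()))
        raise KeyError(f"unknown atlas space {space!r}; known: {known}") from None


def register_space(space: AtlasSpace) -> None:
    """Register a custom space by name (e.g. for an in-house atlas)."""
    _REGISTRY[space.name] = space


def voxel_to_physical(space, v) -> PhysicalPoint:
    """Transform continuous voxel coordinates to physical space."""
    space = get_space(space)
    v = np.asarray(v, dtype=float)
    hom = np.append(v, 1.0) @ space.matrix
    return PhysicalPoint(tuple(hom[:3]), space.axis_order_out, space.units_out)


def physical_to_voxel(space, p) -> np.ndarray:
    """Exact inverse of :func:`voxel_to_physical`."""
    space = get_space(space)
    p = np.asarray(p, dtype=float)
    hom = np.append(p, 1.0) @ np.linalg.inv(space.matrix)
    return hom[:3]


def pixel_to_physical(
    space, a: Anchoring, x: float, y: float, dims: ImageDims
) -> PhysicalPoint:
    """Physical coordinates of an image pixel: composition of the
    pixel-to-voxel plane mapping and the space affine."""
    return voxel_to_physical(space, pixel_to_voxel(a, x, y, dims))
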