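"""Reference-atlas volumes: NIfTI loading, sampling, synthetic fixtures.

Volumes are held as 3D arrays indexed ``(x, y, z)`` under the RAS voxel
convention (x left-to-right, y posterior-to-anterior, z inferior-to-
superior); after loading, voxel coordinates are plain array indices and
the file's affine is forgotten.  Two kinds exist: grayscale ``template``
volumes (MRI, Nissl, ...) and integer ``segmentation`` volumes whose
values are brain-region identifiers resolved through a palette.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "AtlasVolume",
    "Palette",
    "PaletteEntry",
    "load_volume",
    "save_volume",
    "sample",
    "sample_many",
    "make_synthetic_atlas",
]

TEMPLATE = "template"
SEGMENTATION = "segmentation"


@dataclass(frozen=True)
class AtlasVolume:
    """A 3D scalar or label grid in the RAS voxel frame."""

    data: np.ndarray
    kind: str
    name: str = ""
    space: str | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"atlas volume must be 3D, got {data.ndim}D")
        if self.kind not in (TEMPLATE, SEGMENTATION):
            raise ValueError(f"kind must be template or segmentation, got {self.kind!r}")
        if self.kind == SEGMENTATION:
            if not np.issubdtype(data.dtype, np.integer):
                raise ValueError("segmentation volumes must have an integer dtype")
            if data.size and data.min() < 0:
                raise ValueError("segmentation labels must be non-negative")
        else:
            data = data.astype(float, copy=False)
            if not np.all(np.isfinite(data)):
                raise ValueError("template volumes must be finite")
        object.__setattr__(self, "data", data)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class PaletteEntry:
    index: int
    red: int
    green: int
    blue: int
    name: str

    @property
    def rgb(self) -> tuple[int, int, int]:
        return (self.red, self.green, self.blue)


@dataclass(frozen=True)
class Palette:
    """Indexed colors and names for segmentation labels.  Entry ``k`` must
    carry ``index == k`` (the stored index is deliberately redundant)."""

    entries: tuple[PaletteEntry, ...]

    def __post_init__(self) -> None:
        entries = tuple(
            e if isinstance(e, PaletteEntry) else PaletteEntry(*e)
            for e in self.entries
        )
        for pos, entry in enumerate(entries):
            if entry.index != pos:
                raise ValueError(
                    f"palette entry at position {pos} has index {entry.index}; "
                    "index must equal the array position"
                )
            for channel in entry.rgb:
                if not 0 <= channel <= 255:
                    raise ValueError(f"palette color out of range in entry {pos}")
        object.__setattr__(self, "entries", entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, i: int) -> PaletteEntry:
        return self.entries[i]

    def name_of(self, label: int) -> str | None:
        if 0 <= label < len(self.entries):
            return self.entries[label].name
        return None

    def colors(self) -> np.ndarray:
        """(N, 3) uint8 array of the entry colors."""
        return np.array([e.rgb for e in self.entries], dtype=np.uint8)


# -- NIfTI I/O --------------------------------------------------------------

def load_volume(path, kind: str, name: str = "", space: str | None = None) -> AtlasVolume:
    """Load a NIfTI volume and reorient it into the RAS voxel frame.

    Only axis-permutation/flip affines are honored: the file's affine is
    used to detect axis order and direction, the grid is reordered
    accordingly, and voxel coordinates are plain indices thereafter.
    Oblique affines are rejected because the voxel frame is axis-aligned
    by definition.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    rot = np.asarray(img.affine, dtype=float)[:3, :3]
    if np.count_nonzero(np.abs(rot) > 1e-6 * max(1.0, np.abs(rot).max())) != 3:
        raise ValueError(
            "oblique affine: only axis-permutation/flip orientations are supported"
        )
    orientation = nib.orientations.io_orientation(img.affine)
    data = nib.orientations.apply_orientation(data, orientation)
    if kind == SEGMENTATION and not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError("segmentation volume contains non-integer values")
        data = np.round(data).astype(np.int64)
    return AtlasVolume(data, kind, name=name, space=space)


def save_volume(vol: AtlasVolume, path, voxel_size: float = 1.0) -> None:
    """Write a volume as NIfTI-1 with an axis-aligned RAS affine."""
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    data = vol.data
    if data.dtype == np.int64:  # NIfTI-1 has no int64 datatype code
        data = data.astype(np.int32)
    nib.save(nib.Nifti1Image(data, affine), str(path))


# -- sampling ---------------------------------------------------------------

def _nearest_indices(pts: np.ndarray) -> np.ndarray:
    # round half up per axis, the common raster convention
    return np.floor(pts + 0.5).astype(np.int64)


def sample_many(vol: AtlasVolume, pts, method: str = "nearest") -> np.ndarray:
    """Sample the volume at an (N, 3) array of continuous voxel points.

    ``nearest`` rounds each coordinate half-up; ``trilinear`` (templates
    only — labels must never be blended) interpolates the 8 neighbors.
    Any point outside ``[0, N-1]`` on any axis yields background 0.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    if method == "nearest":
        idx = _nearest_indices(pts)
        dims = np.array(vol.dims)
        inside = np.all((idx >= 0) & (idx < dims), axis=1)
        out = np.zeros(len(pts), dtype=vol.data.dtype)
        if inside.any():
            ii = idx[inside]
            out[inside] = vol.data[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out
    if method == "trilinear":
        if vol.kind == SEGMENTATION:
            raise ValueError("trilinear sampling is not allowed on segmentation labels")
        return ndimage.map_coordinates(
            vol.data, pts.T, order=1, mode="constant", cval=0.0
        )
    raise ValueError(f"unknown sampling method {method!r}")


def sample(vol: AtlasVolume, p, method: str = "nearest"):
    """Sample a single continuous voxel point (scalar result)."""
    value = sample_many(vol, np.asarray(p, dtype=float).reshape(1, 3), method)[0]
    return value.item()


# -- synthetic atlas --------------------------------------------------------

def make_synthetic_atlas(
    dims=(64, 80, 56), n_regions: int = 3, seed: int = 0
) -> tuple[AtlasVolume, AtlasVolume, Palette]:
    """Generate a deterministic synthetic atlas for testing and demos.

    The segmentation is a set of nested axis-aligned boxes, label ``k``
    (1..n_regions) nested inside label ``k-1``, on background 0; box ``k``
    starts at ``floor(dim * k / (2 * n_regions + 2))`` on each axis and
    ends symmetrically, so each label's voxel count has a closed form and
    the grid center always carries the innermost label.  The template is
    a smooth separable gradient plus a constant per-region offset, which
    gives every region a distinct mean intensity the way contrast differs
    across structures in an MRI or Nissl volume.  The palette assigns
    each label a distinct random color and the name ``region_k``.
    """
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3 or any(d < 8 for d in dims):
        raise ValueError("dims must be three integers, each >= 8")
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    nx, ny, nz = dims
    seg = np.zeros(dims, dtype=np.int32)
    for k in range(1, n_regions + 1):
        lo = [int(np.floor(d * k / (2 * n_regions + 2))) for d in dims]
        hi = [d - l for d, l in zip(dims, lo)]
        seg[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = k

    gx = np.linspace(0.0, 100.0, nx)[:, None, None]
    gy = np.linspace(0.0, 50.0, ny)[None, :, None]
    gz = np.linspace(0.0, 25.0, nz)[None, None, :]
    template = gx + gy + gz + 20.0 * seg

    rng = np.random.default_rng(seed)
    colors: list[tuple[int, int, int]] = [(0, 0, 0)]
    seen = {(0, 0, 0)}
    while len(colors) < n_regions + 1:
        c = tuple(int(v) for v in rng.integers(16, 256, size=3))
        if c not in seen:
            seen.add(c)
            colors.append(c)
    entries = [PaletteEntry(0, 0, 0, 0, "background")]
    entries += [
        PaletteEntry(k, *colors[k], f"region_{k}") for k in range(1, n_regions + 1)
    ]
    return (
        AtlasVolume(template, TEMPLATE, name="template"),
        AtlasVolume(seg, SEGMENTATION, name="segmentation"),
        Palette(tuple(entries)),
    )


def synthetic_region_volumes(dims, n_regions: int) -> dict[int, int]:
    """Closed-form voxel count per label of :func:`make_synthetic_atlas`."""
    dims = tuple(int(d) for d in dims)

    def box_voxels(k: int) -> int:
        total = 1
        for d in dims:
            lo = int(np.floor(d * k / (2 * n_regions + 2)))
            total *= max(0, d - 2 * lo)
        return total

    counts = {}
    for k in range(0, n_regions + 1):
        outer = box_voxels(k) if k > 0 else int(np.prod(dims))
        inner = box_voxels(k + 1) if k < n_regions else 0
        counts[k] = outer - inner
    return counts
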