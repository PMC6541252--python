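"""Custom atlas plates: oblique resampling, PNG/.flat/palette export.

For each anchored section the atlas volumes are resampled along the
section's plane at the native resolution of the atlas (one plate pixel
per voxel-length along each edge), giving a small "custom atlas slice"
that viewers stretch over the full-resolution section image: plate pixel
``(c_x, c_y)`` corresponds to image pixel ``(x, y)`` through the
separable scaling ``c_x = x*c_w/w``, ``c_y = y*c_h/h``.

Export artifacts per section follow the interchange conventions:

* ``<original filename>-<template name>.png`` — 24-bit truecolor plate
  for every template volume;
* ``<original filename>-<segmentation name>.png`` and ``....flat`` for
  the segmentation: the PNG carries palette colors, the .flat file the
  raw region identifiers;
* one ``<segmentation name>.json`` palette per export folder.

The ``.flat`` raster is big-endian: 1 byte Bpp (bytes per pixel, 1 or
2), two 32-bit dimensions (width then height), then ``Bpp*width*height``
bytes of pixel data, row-major with the top image row first so the flat
file and the PNG align index for index.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .descriptors import SeriesDescriptor
from .geometry import Anchoring, DegenerateAnchoringError, ImageDims, pixel_to_voxel
from .volume import SEGMENTATION, TEMPLATE, AtlasVolume, Palette, sample, sample_many

__all__ = [
    "CustomSlice",
    "FlatFormatError",
    "native_slice_dims",
    "render_slice",
    "image_to_slice_coords",
    "export_series",
    "write_flat",
    "read_flat",
    "write_palette",
    "read_palette",
    "lookup_region",
]

logger = logging.getLogger(__name__)


class FlatFormatError(ValueError):
    """Malformed .flat buffer."""


@dataclass(frozen=True)
class CustomSlice:
    """A resampled atlas plate: ``pixels[row, col]`` with c_h rows."""

    pixels: np.ndarray
    source_volume: str
    anchoring: Anchoring

    @property
    def c_w(self) -> int:
        return self.pixels.shape[1]

    @property
    def c_h(self) -> int:
        return self.pixels.shape[0]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def native_slice_dims(a: Anchoring) -> tuple[int, int]:
    """Plate size at native atlas resolution: one pixel per voxel of edge
    length, ``(round(|u|), round(|v|))``, clamped to at least 1."""
    nu = float(np.linalg.norm(a.u))
    nv = float(np.linalg.norm(a.v))
    if nu == 0.0 or nv == 0.0:
        raise DegenerateAnchoringError("anchoring has a zero-length edge vector")
    return (max(1, _round_half_up(nu)), max(1, _round_half_up(nv)))


def render_slice(
    vol: AtlasVolume,
    a: Anchoring,
    c_w: int | None = None,
    c_h: int | None = None,
    method: str | None = None,
) -> CustomSlice:
    """Resample a volume along an anchoring plane.

    Plate pixel ``(i, j)`` samples the volume at ``o + (i/c_w)*u +
    (j/c_h)*v``, the same fractional weighting that maps image pixels to
    voxels.  Segmentation volumes are always sampled nearest-neighbor.
    """
    if c_w is None or c_h is None:
        c_w, c_h = native_slice_dims(a)
    if method is None:
        method = "nearest"
    if vol.kind == SEGMENTATION and method != "nearest":
        raise ValueError("segmentation plates must use nearest sampling")
    i = np.arange(c_w, dtype=float)
    j = np.arange(c_h, dtype=float)
    jj, ii = np.meshgrid(j, i, indexing="ij")  # rows are j (image rows)
    pts = (
        a.o[None, :]
        + (ii.ravel() / c_w)[:, None] * a.u[None, :]
        + (jj.ravel() / c_h)[:, None] * a.v[None, :]
    )
    values = sample_many(vol, pts, method=method)
    return CustomSlice(values.reshape(c_h, c_w), vol.name, a)


def image_to_slice_coords(
    x: float, y: float, dims: ImageDims, c_w: int, c_h: int
) -> tuple[float, float]:
    """Map an original-image pixel to its plate position: separable
    scaling ``(x*c_w/w, y*c_h/h)``."""
    w, h = dims
    return (x * c_w / w, y * c_h / h)


# -- .flat raster -----------------------------------------------------------

def write_flat(plate) -> bytes:
    """Encode a 2D integer grid (or a segmentation CustomSlice) as .flat
    bytes: Bpp byte, big-endian 32-bit width and height, then row-major
    big-endian pixel data (1 byte per pixel if all labels fit in 8 bits,
    else 2)."""
    grid = plate.pixels if isinstance(plate, CustomSlice) else np.asarray(plate)
    if grid.ndim != 2:
        raise ValueError("flat data must be a 2D grid")
    if not np.issubdtype(grid.dtype, np.integer):
        raise ValueError("flat data must be integer region identifiers")
    if grid.size and (grid.min() < 0 or grid.max() > 0xFFFF):
        raise ValueError("flat labels must fit in an unsigned 16-bit integer")
    bpp = 1 if (grid.size == 0 or grid.max() <= 0xFF) else 2
    h, w = grid.shape
    header = struct.pack(">BII", bpp, w, h)
    dtype = ">u1" if bpp == 1 else ">u2"
    return header + grid.astype(dtype).tobytes(order="C")


def read_flat(buf: bytes) -> np.ndarray:
    """Decode .flat bytes back to an (h, w) integer grid."""
    if len(buf) < 9:
        raise FlatFormatError(f"flat buffer too short for header: {len(buf)} bytes")
    bpp, w, h = struct.unpack(">BII", buf[:9])
    if bpp not in (1, 2):
        raise FlatFormatError(f"unsupported Bpp {bpp}; expected 1 or 2")
    expected = 9 + bpp * w * h
    if len(buf) != expected:
        raise FlatFormatError(
            f"flat buffer has {len(buf)} bytes, expected {expected} "
            f"for Bpp={bpp}, {w}x{h} pixels"
        )
    dtype = ">u1" if bpp == 1 else ">u2"
    grid = np.frombuffer(buf, dtype=dtype, offset=9).reshape(h, w)
    return grid.astype(np.int64)


# -- palette JSON -----------------------------------------------------------

def write_palette(palette: Palette) -> str:
    """Palette as a JSON array of (index, red, green, blue, name) tuples."""
    rows = [[e.index, e.red, e.green, e.blue, e.name] for e in palette.entries]
    return json.dumps(rows)


def read_palette(text: str) -> Palette:
    from .volume import PaletteEntry

    rows = json.loads(text)
    return Palette(
        tuple(
            PaletteEntry(int(i), int(r), int(g), int(b), str(name))
            for i, r, g, b, name in rows
        )
    )


# -- region lookup ----------------------------------------------------------

def lookup_region(
    seg: AtlasVolume,
    palette: Palette,
    a: Anchoring,
    x: float,
    y: float,
    dims: ImageDims,
) -> tuple[int, str | None]:
    """Region identifier and name under an image pixel.

    Samples the segmentation at the nearest voxel of the pixel's plane
    point; pixels mapping outside the volume report background (0).
    """
    label = int(sample(seg, pixel_to_voxel(a, x, y, dims), method="nearest"))
    name = palette.name_of(label)
    if name is None:
        logger.warning("label %d has no palette entry", label)
    return (label, name)


# -- series export ----------------------------------------------------------

def _template_to_rgb(pixels: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Grayscale plate scaled to 0..255 and replicated to truecolor."""
    if hi > lo:
        scaled = np.clip((pixels - lo) / (hi - lo) * 255.0, 0.0, 255.0)
    else:
        scaled = np.zeros_like(pixels, dtype=float)
    gray = scaled.astype(np.uint8)
    return np.stack([gray, gray, gray], axis=-1)


def _make_export_folder(out_root: Path, timestamp: _dt.datetime) -> Path:
    base = out_root / f"Slices-{timestamp:%Y%m%d%H%M%S}"
    folder = base
    bump = 0
    while folder.exists():  # collision: advance the timestamp
        bump += 1
        folder = out_root / f"Slices-{timestamp + _dt.timedelta(seconds=bump):%Y%m%d%H%M%S}"
    folder.mkdir(parents=True)
    return folder


def export_series(
    series: SeriesDescriptor,
    volumes,
    palette: Palette | None,
    out_root,
    timestamp: _dt.datetime | None = None,
    method: str = "nearest",
) -> list[Path]:
    """Export custom atlas plates for every anchored section.

    Creates a timestamped ``Slices-YYYYMMDDHHmmSS`` folder under
    ``out_root`` and writes, per section and volume, the PNG plate (plus
    the .flat raster for segmentations) and one palette JSON per
    segmentation volume.  Sections without an anchoring are skipped with
    a warning.  ``timestamp`` is injectable for reproducible output.
    """
    out_root = Path(out_root)
    out_root.mkdir(parents=True, exist_ok=True)
    folder = _make_export_folder(out_root, timestamp or _dt.datetime.now())
    written: list[Path] = []

    seg_volumes = [v for v in volumes if v.kind == SEGMENTATION]
    if seg_volumes and palette is None:
        raise ValueError("a palette is required to export segmentation volumes")

    for vol in seg_volumes:
        path = folder / f"{vol.name}.json"
        path.write_text(write_palette(palette), encoding="utf-8")
        written.append(path)

    n_done = 0
    for section in series:
        if section.anchoring is None:
            logger.warning(
                "section %s (nr=%d) has no anchoring; skipped", section.filename, section.nr
            )
            continue
        c_w, c_h = native_slice_dims(section.anchoring)
        for vol in volumes:
            plate = render_slice(
                vol,
                section.anchoring,
                c_w,
                c_h,
                method="nearest" if vol.kind == SEGMENTATION else method,
            )
            png_path = folder / f"{section.filename}-{vol.name}.png"
            if vol.kind == TEMPLATE:
                lo, hi = float(vol.data.min()), float(vol.data.max())
                rgb = _template_to_rgb(plate.pixels, lo, hi)
            else:
                rgb = palette.colors()[plate.pixels.astype(np.int64)]
            Image.fromarray(rgb, mode="RGB").save(png_path)
            written.append(png_path)
            if vol.kind == SEGMENTATION:
                flat_path = folder / f"{section.filename}-{vol.name}.flat"
                flat_path.write_bytes(write_flat(plate))
                written.append(flat_path)
        n_done += 1
        logger.info("exported %d/%d sections", n_done, len(series))
    return written
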