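"""Propagating anchorings across a section series.

Anchoring a whole series by hand would defeat the point of a fast tool:
instead the user anchors a few sections with clear landmarks, and the
spacing of the remaining sections is recalculated automatically every
time another section is verified.  This module implements that
redistribution plus the even initial distribution used before any
section has been anchored.

Estimation is componentwise-linear in the serial number: for a section
strictly between two verified ones, each of o, u, v is interpolated with
parameter ``t = (nr - nr_a) / (nr_b - nr_a)``; outside the verified
range the two nearest verified anchors are extrapolated linearly.  Serial
numbers, not list positions, drive the parameter, so gaps in the imaged
series (e.g. every 4th section) are respected.  Interpolation reproduces
the verified endpoints bit for bit, which is the compatibility contract.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .descriptors import (
    STATUS_ESTIMATED,
    STATUS_VERIFIED,
    SectionImage,
    SeriesDescriptor,
)
from .geometry import Anchoring

__all__ = [
    "PropagationConfig",
    "initial_distribution",
    "propagate",
    "restore_estimates",
]

_AXIS_INDEX = {"sagittal": 0, "coronal": 1, "horizontal": 2}


@dataclass(frozen=True)
class PropagationConfig:
    """Knobs for the redistribution.

    ``default_axis`` picks the sectioning plane family for the initial
    distribution and the zero-pose edge vectors.  ``default_spacing``
    (voxels per unit serial-number difference) is only used when exactly
    one verified anchor exists; None means "atlas extent along the
    default axis divided by N+1", mirroring the even initial spacing.
    ``atlas_dims``, when given, lets extrapolated planes be clamped back
    so they still intersect the atlas bounding box.
    """

    default_axis: str = "coronal"
    default_spacing: float | None = None
    atlas_dims: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.default_axis not in _AXIS_INDEX:
            raise ValueError(f"unknown axis {self.default_axis!r}")
        if self.default_spacing is not None and not self.default_spacing > 0:
            raise ValueError("default_spacing must be positive")


def zero_pose_anchoring(axis: str, position: float, atlas_dims) -> Anchoring:
    """The untilted full-extent plane of an axis family at a position.

    Coronal (plane y = position): image left = subject left, top =
    superior.  Sagittal (x = position): image left = anterior, top =
    superior.  Horizontal (z = position): image top = anterior.
    """
    nx, ny, nz = (float(d) for d in atlas_dims)
    if axis == "coronal":
        return Anchoring((0.0, position, nz), (nx, 0.0, 0.0), (0.0, 0.0, -nz))
    if axis == "sagittal":
        return Anchoring((position, ny, nz), (0.0, -ny, 0.0), (0.0, 0.0, -nz))
    if axis == "horizontal":
        return Anchoring((0.0, ny, position), (nx, 0.0, 0.0), (0.0, -ny, 0.0))
    raise ValueError(f"unknown axis {axis!r}")


def initial_distribution(
    series: SeriesDescriptor, atlas_dims, cfg: PropagationConfig | None = None
) -> SeriesDescriptor:
    """Spread a fresh series evenly along the default axis.

    The N sections get untilted planes at fractional positions
    ``(N - k + 0.5) / N`` of the axis extent for rank k = 1..N, so the
    first section sits most anterior for coronal series.  All anchorings
    are marked estimated.
    """
    cfg = cfg or PropagationConfig()
    if len(series) == 0:
        raise ValueError("cannot distribute an empty series")
    n = len(series)
    extent = float(atlas_dims[_AXIS_INDEX[cfg.default_axis]])
    out = []
    for rank, section in enumerate(series, start=1):
        position = (n - rank + 0.5) / n * extent
        a = zero_pose_anchoring(cfg.default_axis, position, atlas_dims)
        out.append(replace(section, anchoring=a, status=STATUS_ESTIMATED))
    return series.with_slices(out)


def _lerp(a: Anchoring, b: Anchoring, t: float) -> Anchoring:
    if t == 0.0:  # preserve endpoints bit for bit
        return a
    if t == 1.0:
        return b
    return Anchoring(
        a.o + t * (b.o - a.o),
        a.u + t * (b.u - a.u),
        a.v + t * (b.v - a.v),
    )


def _clamp_to_atlas(a: Anchoring, atlas_dims) -> Anchoring:
    """Translate a plane so its center lies inside the atlas box (then the
    plane necessarily intersects the box)."""
    center = a.o + (a.u + a.v) / 2.0
    clamped = np.clip(center, 0.0, np.asarray(atlas_dims, dtype=float))
    if np.array_equal(clamped, center):
        return a
    return Anchoring(a.o + (clamped - center), a.u, a.v)


def propagate(
    series: SeriesDescriptor, cfg: PropagationConfig | None = None
) -> SeriesDescriptor:
    """Estimate anchorings for unverified sections from the verified ones.

    Verified sections pass through untouched.  Between two verified
    sections, o, u and v are interpolated linearly in the serial number;
    outside the verified range they are extrapolated from the two nearest
    verified anchors (and clamped to intersect the atlas box when the
    config carries atlas dims).  With a single verified anchor, u and v
    are copied and o is translated along the plane unit normal by
    ``(nr - nr_verified) * default_spacing``.  Estimates are marked
    estimated; running propagate again is a no-op.
    """
    cfg = cfg or PropagationConfig()
    verified = [s for s in series if s.status == STATUS_VERIFIED and s.anchoring]
    if not verified:
        raise ValueError(
            "no verified anchorings to propagate from; "
            "use initial_distribution for a fresh series"
        )
    nrs = [s.nr for s in verified]

    spacing = cfg.default_spacing
    if spacing is None and cfg.atlas_dims is not None:
        extent = float(cfg.atlas_dims[_AXIS_INDEX[cfg.default_axis]])
        spacing = extent / (len(series) + 1)

    out: list[SectionImage] = []
    for section in series:
        if section.status == STATUS_VERIFIED and section.anchoring is not None:
            out.append(section)
            continue
        a = _estimate(section.nr, verified, nrs, spacing, cfg)
        out.append(replace(section, anchoring=a, status=STATUS_ESTIMATED))
    return series.with_slices(out)


def _estimate(nr, verified, nrs, spacing, cfg) -> Anchoring:
    if len(verified) == 1:
        anchor = verified[0]
        if spacing is None:
            spacing = 1.0
        shift = (nr - anchor.nr) * spacing
        a = anchor.anchoring
        return Anchoring(a.o + shift * a.normal, a.u, a.v)

    extrapolated = False
    if nr <= nrs[0]:
        lo, hi = verified[0], verified[1]
        extrapolated = nr < nrs[0]
    elif nr >= nrs[-1]:
        lo, hi = verified[-2], verified[-1]
        extrapolated = nr > nrs[-1]
    else:
        idx = int(np.searchsorted(nrs, nr, side="right")) - 1
        lo, hi = verified[idx], verified[idx + 1]
    t = (nr - lo.nr) / (hi.nr - lo.nr)
    a = _lerp(lo.anchoring, hi.anchoring, t)
    if extrapolated and cfg.atlas_dims is not None:
        a = _clamp_to_atlas(a, cfg.atlas_dims)
    return a


def restore_estimates(series: SeriesDescriptor) -> SeriesDescriptor:
    """Drop estimated anchorings, keeping only the user-verified ones, so
    propagation can be recomputed from the verified set alone."""
    out = [
        s if s.status == STATUS_VERIFIED else replace(s, anchoring=None)
        for s in series
    ]
    return series.with_slices(out)
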