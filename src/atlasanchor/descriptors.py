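"""Series descriptors: the XML/JSON interchange files and folder scanning.

A series descriptor names an ordered set of section images and, for the
sections a user has anchored, their o/u/v vectors.  Two dialects exist:

* XML: ``<series name="..."><slice filename="..." nr="..." width="..."
  height="..." anchoring="ox=...&oy=...&...&vz=..."/></series>``.
  The anchoring attribute is a URL-style key=value string with the nine
  components ox..vz.  Stored XML carries only user-verified anchorings.
* JSON: ``{"name": ..., "slices": [{"nr": ..., "filename": ...,
  "width": ..., "height": ..., "anchoring": [9 floats]}]}`` with the
  anchoring array positionally in ox, oy, oz, ux, uy, uz, vx, vy, vz
  order.  Slices may carry an optional "status" extension field
  ("estimated" or "verified"); it defaults to verified on read.

Readers are liberal (optional whitespace around '=', percent-encoding);
writers are conservative (no spaces, shortest-repr floats so values like
334.82142136461607 survive round trips digit for digit).
"""

from __future__ import annotations

import json
import logging
import re
import urllib.parse
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

from .geometry import Anchoring

__all__ = [
    "SectionImage",
    "SeriesDescriptor",
    "DescriptorError",
    "parse_xml",
    "write_xml",
    "parse_json",
    "write_json",
    "parse_serial_number",
    "build_descriptor",
    "scan_folder",
    "read_descriptor",
    "write_descriptor",
]

logger = logging.getLogger(__name__)

STATUS_ESTIMATED = "estimated"
STATUS_VERIFIED = "verified"

_ANCHOR_KEYS = ("ox", "oy", "oz", "ux", "uy", "uz", "vx", "vy", "vz")


class DescriptorError(ValueError):
    """Malformed series descriptor content."""


@dataclass(frozen=True)
class SectionImage:
    """One section: filename, serial number, full-resolution pixel size,
    and (optionally) its anchoring with a verification status."""

    filename: str
    nr: int
    width: int
    height: int
    anchoring: Anchoring | None = None
    status: str = STATUS_ESTIMATED

    def __post_init__(self) -> None:
        if self.nr < 0:
            raise DescriptorError(f"slice {self.filename!r}: nr must be >= 0")
        if self.width < 1 or self.height < 1:
            raise DescriptorError(
                f"slice {self.filename!r}: width/height must be >= 1"
            )
        if self.status not in (STATUS_ESTIMATED, STATUS_VERIFIED):
            raise DescriptorError(
                f"slice {self.filename!r}: bad status {self.status!r}"
            )

    @property
    def dims(self) -> tuple[int, int]:
        return (self.width, self.height)


@dataclass(frozen=True)
class SeriesDescriptor:
    """Named, nr-ordered collection of section images."""

    name: str
    slices: tuple[SectionImage, ...] = ()

    def __post_init__(self) -> None:
        slices = tuple(sorted(self.slices, key=lambda s: s.nr))
        nrs = [s.nr for s in slices]
        dupes = sorted({n for n in nrs if nrs.count(n) > 1})
        if dupes:
            raise DescriptorError(f"duplicate slice nr(s): {dupes}")
        object.__setattr__(self, "slices", slices)

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self):
        return iter(self.slices)

    def get(self, nr: int) -> SectionImage:
        for s in self.slices:
            if s.nr == nr:
                return s
        raise KeyError(f"no slice with nr={nr}")

    def with_slices(self, slices) -> "SeriesDescriptor":
        return SeriesDescriptor(self.name, tuple(slices))


# -- anchoring string dialect ----------------------------------------------

def _parse_anchoring_string(text: str, where: str) -> Anchoring:
    values: dict[str, float] = {}
    for part in text.split("&"):
        part = urllib.parse.unquote(part)
        if not part.strip():
            continue
        if "=" not in part:
            raise DescriptorError(f"{where}: malformed anchoring token {part!r}")
        key, _, raw = part.partition("=")
        key = key.strip()
        raw = raw.strip()
        if key not in _ANCHOR_KEYS:
            raise DescriptorError(f"{where}: unknown anchoring key {key!r}")
        try:
            values[key] = float(raw)
        except ValueError:
            raise DescriptorError(
                f"{where}: non-numeric anchoring component {key}={raw!r}"
            ) from None
    missing = [k for k in _ANCHOR_KEYS if k not in values]
    if missing:
        raise DescriptorError(
            f"{where}: anchoring is missing component(s) {missing}"
        )
    return Anchoring.from_flat([values[k] for k in _ANCHOR_KEYS])


def _format_anchoring_string(a: Anchoring) -> str:
    return "&".join(
        f"{key}={_fmt(value)}" for key, value in zip(_ANCHOR_KEYS, a.as_flat())
    )


def _fmt(value: float) -> str:
    """Shortest decimal representation that round-trips the double."""
    text = repr(float(value))
    return text[:-2] if text.endswith(".0") else text


# -- XML dialect ------------------------------------------------------------

def parse_xml(text: str) -> SeriesDescriptor:
    """Parse an XML series descriptor.

    Anchored slices are marked verified (stored XML contains only
    user-approved anchorings); slices without an anchoring attribute are
    estimated.
    """
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise DescriptorError(f"not well-formed XML: {exc}") from exc
    if root.tag != "series":
        raise DescriptorError(f"expected <series> root, got <{root.tag}>")
    name = root.get("name", "")
    slices = []
    for elem in root.iter("slice"):
        where = f"slice {elem.get('filename') or elem.get('nr') or '?'}"
        for attr in ("filename", "nr", "width", "height"):
            if elem.get(attr) is None:
                raise DescriptorError(f"{where}: missing attribute {attr!r}")
        try:
            nr = int(elem.get("nr"))
            width = int(elem.get("width"))
            height = int(elem.get("height"))
        except ValueError as exc:
            raise DescriptorError(f"{where}: {exc}") from None
        anchoring_text = elem.get("anchoring")
        if anchoring_text is None:
            anchoring, status = None, STATUS_ESTIMATED
        else:
            anchoring = _parse_anchoring_string(anchoring_text, where)
            # optional extension attribute; stored descriptors omit it and
            # carry only user-verified anchorings
            status = elem.get("status", STATUS_VERIFIED)
        slices.append(
            SectionImage(elem.get("filename"), nr, width, height, anchoring, status)
        )
    return SeriesDescriptor(name, tuple(slices))


def write_xml(series: SeriesDescriptor, include_estimates: bool = False) -> str:
    """Serialize to XML.  By default only verified anchorings are written,
    matching the stored-descriptor convention; ``include_estimates=True``
    also writes estimated ones (tagged with a non-standard status
    attribute)."""
    root = ET.Element("series", {"name": series.name})
    for s in series.slices:
        attrs = {
            "filename": s.filename,
            "nr": str(s.nr),
            "width": str(s.width),
            "height": str(s.height),
        }
        if s.anchoring is not None and (
            s.status == STATUS_VERIFIED or include_estimates
        ):
            attrs["anchoring"] = _format_anchoring_string(s.anchoring)
            if include_estimates and s.status == STATUS_ESTIMATED:
                attrs["status"] = s.status
        ET.SubElement(root, "slice", attrs)
    body = ET.tostring(root, encoding="unicode")
    return "<?xml version='1.0' encoding='UTF-8'?>\n" + body


# -- JSON dialect -----------------------------------------------------------

def parse_json(text: str) -> SeriesDescriptor:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise DescriptorError(f"not valid JSON: {exc}") from exc
    if not isinstance(payload, dict) or "slices" not in payload:
        raise DescriptorError('JSON descriptor needs "name" and "slices"')
    slices = []
    for entry in payload["slices"]:
        where = f"slice {entry.get('filename') or entry.get('nr') or '?'}"
        for key in ("filename", "nr", "width", "height"):
            if key not in entry:
                raise DescriptorError(f"{where}: missing field {key!r}")
        anchoring = None
        if "anchoring" in entry and entry["anchoring"] is not None:
            flat = entry["anchoring"]
            if len(flat) != 9:
                raise DescriptorError(
                    f"{where}: anchoring array has {len(flat)} values, expected 9"
                )
            anchoring = Anchoring.from_flat([float(x) for x in flat])
        status = entry.get(
            "status", STATUS_VERIFIED if anchoring is not None else STATUS_ESTIMATED
        )
        slices.append(
            SectionImage(
                entry["filename"],
                int(entry["nr"]),
                int(entry["width"]),
                int(entry["height"]),
                anchoring,
                status,
            )
        )
    return SeriesDescriptor(payload.get("name", ""), tuple(slices))


def write_json(series: SeriesDescriptor, include_estimates: bool = False) -> str:
    entries = []
    for s in series.slices:
        entry: dict = {
            "nr": s.nr,
            "filename": s.filename,
            "width": s.width,
            "height": s.height,
        }
        if s.anchoring is not None and (
            s.status == STATUS_VERIFIED or include_estimates
        ):
            entry["anchoring"] = s.anchoring.as_flat()
            if include_estimates and s.status == STATUS_ESTIMATED:
                entry["status"] = s.status
        entries.append(entry)
    return json.dumps({"name": series.name, "slices": entries}, indent=1)


def read_descriptor(path) -> SeriesDescriptor:
    """Read a descriptor, dispatching on the .xml/.json file extension."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return parse_json(text)
    return parse_xml(text)


def write_descriptor(series: SeriesDescriptor, path, include_estimates=False) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        text = write_json(series, include_estimates=include_estimates)
    else:
        text = write_xml(series, include_estimates=include_estimates)
    path.write_text(text, encoding="utf-8")


# -- folder scanning (FileBuilder equivalent) -------------------------------

_DIGITS = re.compile(r"\d+")


def parse_serial_number(filename: str) -> int | None:
    """Serial number from a filename: the last run of decimal digits in
    the basename before the extension (``Sample_ID_s001.tif`` -> 1), or
    None if the name contains no digits."""
    stem = Path(filename).stem
    runs = _DIGITS.findall(stem)
    return int(runs[-1]) if runs else None


def build_descriptor(
    listing, name: str, strict: bool = False
) -> SeriesDescriptor:
    """Build a descriptor from ``(filename, width, height)`` triples.

    Slices are ordered by the serial number parsed from each filename.
    When no filename carries a number, sequential numbers 1..N are
    assigned in listing order after a warning (``strict=True`` turns any
    unparsable name into an error instead).
    """
    listing = list(listing)
    if not listing:
        raise DescriptorError("cannot build a descriptor from an empty listing")
    parsed = [parse_serial_number(fn) for fn, _, _ in listing]
    missing = [fn for (fn, _, _), nr in zip(listing, parsed) if nr is None]
    if missing:
        if strict:
            raise DescriptorError(
                f"no serial number parsable from: {missing}"
            )
        logger.warning(
            "no serial numbers in %d filename(s) (%s); assigning sequential "
            "numbers in listing order",
            len(missing),
            ", ".join(missing[:5]),
        )
        parsed = list(range(1, len(listing) + 1))
    dupes = sorted({n for n in parsed if parsed.count(n) > 1})
    if dupes:
        offenders = [fn for (fn, _, _), nr in zip(listing, parsed) if nr in dupes]
        raise DescriptorError(
            f"duplicate serial number(s) {dupes} from files {offenders}"
        )
    slices = tuple(
        SectionImage(fn, nr, w, h)
        for (fn, w, h), nr in zip(listing, parsed)
    )
    return SeriesDescriptor(name, slices)


def scan_folder(folder, name: str | None = None, strict: bool = False,
                patterns: tuple[str, ...] = ("*.png", "*.jpg", "*.jpeg")) -> SeriesDescriptor:
    """Scan an image folder and build a descriptor from the PNG/JPEG files
    found, reading pixel dimensions from the image headers."""
    from PIL import Image

    folder = Path(folder)
    files: list[Path] = []
    for pattern in patterns:
        files.extend(folder.glob(pattern))
    files = sorted(set(files))
    listing = []
    for path in files:
        with Image.open(path) as img:
            listing.append((path.name, img.width, img.height))
    return build_descriptor(listing, name or folder.name, strict=strict)
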