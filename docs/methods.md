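# Methods

## The anchoring model

A digitized brain section carries no intrinsic 3D information.
`atlasanchor` places each section in a reference atlas by an affine
"anchoring": three vectors in atlas-voxel units,

* **o** — from the atlas origin to the top-left corner of the matching
  atlas slice,
* **u** — the slice's horizontal edge (top-left → top-right),
* **v** — its vertical edge (top-left → bottom-left).

Pixel (x, y) of a w×h image maps to the continuous voxel coordinate

    p(x, y) = o + (x/w)·u + (y/h)·v,

so the four image corners land on o, o+u, o+v and o+u+v.  Equivalently
`(x/w, y/h, 1) @ M` with the 3×3 matrix M whose rows are u, v, o.  Pixel
weights use x/w, not x/(w−1): this is the interchange convention, and its
consequence — pixel w−1 maps slightly short of o+u, and sample weights on
an N-pixel plate run 0 … (N−1)/N — is accepted throughout rather than
papered over.  The section image itself is never resampled or distorted;
only the atlas is.

The voxel frame is RAS: x left→right, y posterior→anterior, z
inferior→superior, origin at the bottom-left corner of the most anterior
coronal plane.  All geometry is double precision.

`voxel_to_pixel` inverts the mapping by decomposing p − o = s·u + t·v +
d·n̂ with n̂ = (u×v)/|u×v| (this sign convention is fixed; for the default
coronal plane n̂ points anterior).  It requires a non-degenerate plane
(|u×v| > 0); `pixel_to_voxel` tolerates degeneracy since it only ever
adds vectors.

## Pose parameterization (tilt angles)

Users think in terms of a cutting position plus dorsoventral (DV) and
mediolateral (ML) tilts.  No published convention fixes the angle math,
so the package declares one:

* The zero pose at coronal position y0 on an (Nx, Ny, Nz) atlas is
  o = (0, y0, Nz), u = (Nx, 0, 0), v = (0, 0, −Nz): image left =
  subject's left, image top = superior (screen y grows downward).
* Tilts are intrinsic rotations through the plane center: DV about the
  image-horizontal (u) axis, then ML about the tilted image-vertical (v)
  axis.  Positive DV moves the image top anterior; positive ML moves the
  image-right edge anterior.  Users preferring the opposite signs can
  negate the angles.

With this convention the sagittal projection of the plane normal makes
exactly the DV angle with the coronal normal, while the
horizontal-projection angle equals atan(tan ML / cos DV) — exactly ML
only when DV = 0.  `pose_to_anchoring`/`anchoring_to_pose` are mutual
inverses for planes expressible in the convention; planes tilted ≥ 90°
from coronal are rejected.  Angles live in (−90°, 90°), scales are
relative to the full atlas extents.

## Physical-space transforms

Voxel→physical affines for the two published spaces are stored as their
printed 4×4 row-vector matrices, never re-derived from resolution
constants:

* Allen CCFv3 (mouse): 25 μm voxels, output in μm with PIR axis order —
  x_a = 13175 − 25·y_v, y_a = 7975 − 25·z_v, z_a = 25·x_v.
* Waxholm Space (rat): 0.0390625 mm voxels, output in mm, RAS order —
  (x,y,z)_w = 0.0390625·(x,y,z)_v − (9.53125, 24.3359375, 9.6875).
  (The often-quoted "40 μm" WHS pixel is a rounded figure; the matrix
  value 0.0390625 mm = 39.0625 μm is authoritative here.)

Outputs are `PhysicalPoint` objects carrying axis labels and units so a
PIR triple cannot be silently read as RAS.  Custom spaces can be
registered with any invertible 4×4 matrix.

## Descriptors

XML and JSON series descriptors are information-equivalent.  Readers are
liberal: optional whitespace around `=` in the anchoring string, URL
percent-encoding, missing anchoring attributes.  Writers are
conservative: no spaces, shortest-round-trip float formatting (`repr`),
UTF-8, and — matching the stored-file convention — only user-verified
anchorings unless `include_estimates` is set, in which case estimated
ones are written with a non-standard `status` attribute/field (an
extension this package documents and reads back).

Serial numbers are parsed as the last run of decimal digits in the
basename (`Sample_ID_s001.tif` → 1).  Folder scanning stores the pixel
dimensions of the files it reads; width/height must be the dimensions
the anchoring refers to, so scan the same files you anchor.

## Volumes and sampling

NIfTI volumes are reoriented on load into the RAS voxel frame using the
file's affine for axis order/flips only; oblique affines are rejected
because the voxel frame is axis-aligned by definition.  After loading,
voxel coordinates are plain array indices.

Nearest sampling rounds half-up per axis (`floor(c + 0.5)`), a fixed,
deterministic raster convention.  Trilinear sampling (templates only —
region labels must never be blended) is standard 8-neighbor
interpolation via `scipy.ndimage.map_coordinates(order=1)`.  Any point
outside [0, N−1] on any axis yields background 0.  Nearest is the
default everywhere for parity between templates and segmentations.

## Plate rendering and export

A plate is rendered at the native atlas resolution: c_w = round(|u|),
c_h = round(|v|) pixels (≥ 1), with plate pixel (i, j) sampling
o + (i/c_w)·u + (j/c_h)·v — the same fractional weighting as the image
mapping, so the plate stretched over the image (c_x = x·c_w/w,
c_y = y·c_h/h, separable) agrees with direct per-pixel sampling to
within one voxel.  One subtlety follows from the 0 … (N−1)/N weights: a
full-extent coronal plane with o_z = Nz samples z = Nz on its top plate
row, half a step outside the grid, so that row renders background; the
axis-aligned tests encode exactly this.

Export writes, per section and volume, a 24-bit truecolor PNG (templates
are min–max scaled to 0–255 and replicated across channels; computed
per volume, deterministic), and for segmentations additionally a `.flat`
raster of raw region ids plus one palette JSON per volume.  The `.flat`
layout is: 1 byte Bpp (1 if all labels ≤ 255, else 2; labels > 65535 are
rejected), big-endian uint32 width and height, then Bpp·w·h bytes of
big-endian pixels, row-major with the top image row first so `.flat` and
PNG align index for index.  The palette is a JSON array of
(index, R, G, B, name) tuples; the stored index must equal the array
position and this redundancy is enforced on both read and write.  The
export folder is `Slices-YYYYMMDDHHmmSS`; the timestamp is injectable
for reproducible runs and advances by one second on collision.

## Propagation

Anchoring every section by hand defeats the tool's purpose; instead the
verified sections drive the rest.  Estimation is componentwise-linear in
the serial number (not list rank, so unsampled sections are respected):
between two verified anchors, o, u and v are interpolated with
t = (nr−a)/(b−a); outside the verified range the nearest verified pair
is extrapolated linearly, with the plane center clamped into the atlas
box when atlas dims are supplied (a plane whose center is inside the box
necessarily intersects it).  With a single verified anchor, u and v are
copied and o is translated along n̂ by (nr − nr_a)·spacing; spacing
defaults to (axis extent)/(N+1), mirroring the even initial
distribution, and can be negated to reverse direction.  Interpolating
pose angles instead of raw vectors was rejected: componentwise vectors
reproduce endpoints bit for bit and approximate angle interpolation well
for the small tilt differences typical between neighboring anchors; for
large angle gaps the interpolated |u| shrinks slightly (chord vs arc), a
documented limitation.

A fresh series with no anchors gets the even initial distribution:
rank-k of N sections (by nr) at fractional position (N−k+0.5)/N of the
axis extent, first section most anterior for coronal series, all planes
untilted and marked estimated.

## Synthetic atlas

`make_synthetic_atlas(dims=(64, 80, 56), n_regions=3, seed)` builds the
test fixture standing in for the real mouse/rat volumes: a segmentation
of nested axis-aligned boxes (label k starting at floor(dim·k/(2n+2))
per axis, so per-label voxel counts have a closed form and the grid
center carries the innermost label) and a template of smooth separable
gradients plus a 20-unit per-region offset, mimicking region-dependent
contrast.  It is deterministic per seed (colors are the only random
element).  It emulates what the pipeline needs — a labeled volume with
known geometry and a co-registered scalar volume — and deliberately not
the anatomy, noise, or intensity statistics of real MRI/Nissl data:
passing tests demonstrate geometric and format correctness, not
registration quality on real brains.  The default 64×80×56 grid keeps
the full pipeline around a second; the math is resolution-independent.

## Numerical choices

* Double precision throughout; no tolerance is applied where exactness
  is achievable (corner identities, matrix agreement, flat round-trips).
* round-half-up (`floor(c+0.5)`) everywhere a continuous coordinate
  becomes an index: volume sampling and plate sizing share the rule.
* Linear interpolation is computed as a + t·(b−a), which reproduces the
  endpoint at t = 0 exactly (t ∈ {0, 1} short-circuit to the verified
  anchors bit for bit).
* Degenerate anchorings (collinear u, v) raise a dedicated error in
  every operation that needs a plane; `pixel_to_voxel` alone accepts
  them.

## Known limitations

* Affine-only: no nonlinear refinement of the section-to-atlas fit.
* Propagation redistributes user anchorings; it performs no
  image-content registration.
* Only axis-aligned NIfTI orientations load; resample oblique volumes
  upstream.
* `.flat` caps labels at 65535 (2-byte pixels), per the format.
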