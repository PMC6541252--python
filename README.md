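# atlasanchor

Registering series of 2D microscopic brain-section images to a 3D
reference atlas is a bottleneck in rodent neuroanatomy: sections are
routinely cut at angles deviating from the atlas's standard planes, so
matching them against fixed 2D atlas plates is inaccurate and slow.
`atlasanchor` implements the computational core of the anchoring
approach behind tools like QuickNII, headlessly: instead of deforming
the experimental images, each section is assigned an arbitrary oblique
plane through the atlas volume, and customized atlas plates are
generated along that plane.

The placement of a w×h section image is encoded by three vectors in
atlas-voxel units — **o** (top-left corner of the matching atlas slice),
**u** (horizontal edge) and **v** (vertical edge) — so that image pixel
(x, y) corresponds to the continuous voxel coordinate

    o + (x/w)·u + (y/h)·v .

On top of this model the package provides:

* **Geometry** — pixel↔voxel mapping, the 3×3 anchoring matrix, and a
  pose parameterization (position, DV/ML tilt angles, scales).
* **Reference spaces** — the published voxel→physical 4×4 affines for
  the Allen Mouse CCFv3 (25 μm, PIR) and Waxholm rat space
  (0.0390625 mm, RAS), plus custom space registration.
* **Descriptors** — reading/writing the XML and JSON series-descriptor
  dialects losslessly, and building descriptors from image folders with
  serial numbers parsed from filenames.
* **Volumes** — NIfTI atlas loading under the RAS voxel convention,
  nearest/trilinear sampling, and a deterministic synthetic atlas
  generator for testing without the (large) real volumes.
* **Plate export** — resampling every atlas volume along each section's
  plane at native atlas resolution; writing truecolor PNG plates, raw
  `.flat` label rasters (big-endian: Bpp byte, two uint32 dims, pixels)
  and the palette JSON; region-name lookup under any image pixel.
* **Propagation** — even initial distribution of a fresh series and
  serial-number-linear re-estimation of unanchored sections from the
  user-verified ones.

See `docs/methods.md` for the model conventions and numerical choices.

## Worked example

The package bundles the format's two-slice reference descriptor.  Slice
nr 2 is a 24723×18561 px image anchored at o = (312.2, 533.8, 218.4)
with u = (−185.7, −35.5, 6.6), v = (−4.6, −7.5, −171.4):

```python
>>> import atlasanchor as aa
>>> series = aa.parse_xml(aa.demo_descriptor_text("xml"))
>>> s2 = series.get(2)
>>> aa.pixel_to_voxel(s2.anchoring, 0, 0, s2.dims)          # top-left = o
array([312.2, 533.8, 218.4])
>>> aa.pixel_to_voxel(s2.anchoring, s2.width, s2.height, s2.dims)  # o+u+v
array([121.9, 490.8,  53.6])
>>> aa.native_slice_dims(s2.anchoring)   # plate size: (round|u|, round|v|)
(189, 172)
>>> aa.pixel_to_physical("allen_ccfv3", s2.anchoring, 0, 0, s2.dims).labelled()
{'P': -169.99999999999818, 'I': 2515.0, 'R': 7805.0}
```

The top-left pixel sits at voxel (312.2, 533.8, 218.4); the
bottom-right corner lands on o+u+v; the atlas plate for this section is
189×172 px (one pixel per voxel of edge length); and in Allen CCFv3
physical coordinates the top-left pixel is at −170 μm posterior,
2515 μm inferior, 7805 μm right.

The same workflow from the shell, end to end on a synthetic atlas:

```sh
atlasanchor make-fixture --dims 64,80,56 --regions 3 --seed 7 --out atlas/
atlasanchor build-descriptor images/ --out series.xml
atlasanchor propagate series.xml --atlas-dims 64,80,56 \
    --out series_est.xml --include-estimates
atlasanchor export-slices series_est.xml --atlas-dir atlas/ --out plates/
atlasanchor transform --space allen 312.2 533.8 218.4
# -170 2515 7805 (PIR, um)
```

`export-slices` creates a `Slices-YYYYMMDDHHmmSS` folder holding, per
section, one PNG per template, PNG + `.flat` for the segmentation, and
one palette JSON.

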