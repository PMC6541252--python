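"""atlasanchor: anchor serial 2D brain-section images to 3D reference atlases.

A section image is placed in an atlas by three voxel-space vectors
(o: top-left corner, u: horizontal edge, v: vertical edge).  The package
reads and writes QuickNII-compatible XML/JSON series descriptors,
converts between image pixels, atlas voxels and physical coordinates
(Allen CCFv3, Waxholm Space), resamples atlas volumes along arbitrary
oblique section planes to produce matching atlas plates (PNG, .flat
label raster, palette JSON), and propagates anchorings across a series
from the sections a user has verified.
"""

from importlib import resources as _resources

from .descriptors import (
    DescriptorError,
    SectionImage,
    SeriesDescriptor,
    build_descriptor,
    parse_json,
    parse_serial_number,
    parse_xml,
    read_descriptor,
    scan_folder,
    write_descriptor,
    write_json,
    write_xml,
)
from .export import (
    CustomSlice,
    FlatFormatError,
    export_series,
    image_to_slice_coords,
    lookup_region,
    native_slice_dims,
    read_flat,
    read_palette,
    render_slice,
    write_flat,
    write_palette,
)
from .geometry import (
    Anchoring,
    DegenerateAnchoringError,
    ImageDims,
    Pose,
    anchoring_matrix,
    anchoring_to_pose,
    pixel_to_voxel,
    pose_to_anchoring,
    voxel_to_pixel,
)
from .propagation import (
    PropagationConfig,
    initial_distribution,
    propagate,
    restore_estimates,
)
from .spaces import (
    ALLEN_CCFV3,
    WHS_RAT,
    AtlasSpace,
    PhysicalPoint,
    get_space,
    physical_to_voxel,
    pixel_to_physical,
    register_space,
    voxel_to_physical,
)
from .volume import (
    AtlasVolume,
    Palette,
    PaletteEntry,
    load_volume,
    make_synthetic_atlas,
    sample,
    sample_many,
    save_volume,
)

__version__ = "0.1.0"


def demo_descriptor_text(dialect: str = "xml") -> str:
    """The bundled two-slice reference descriptor (``xml`` or ``json``),
    the standard worked example of the interchange format."""
    if dialect not in ("xml", "json"):
        raise ValueError("dialect must be 'xml' or 'json'")
    ref = _resources.files("atlasanchor.data") / f"demo_series.{dialect}"
    return ref.read_text(encoding="utf-8")
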