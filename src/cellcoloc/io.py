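"""Image, mask and ROI input: the containers every other stage consumes.

The input contract for colocalization analysis: monochromatic (single sample
per pixel) 8/16/32-bit TIFF images, one stack per channel, all images in an
experiment sharing dimensions and stack order.  ROI sets (hand-drawn cell
outlines, e.g. on DIC images where thresholding fails) are read from ImageJ
``.roi`` files or ``RoiSet.zip`` archives.

Coordinate convention
---------------------
Internally everything is 0-based ``(row, col)`` with pixel *centers* at
integer coordinates: pixel ``(r, c)`` occupies the square
``[r-0.5, r+0.5] x [c-0.5, c+0.5]``.  ImageJ ROI vertices live on the pixel
*corner* lattice (origin at the top-left corner of pixel (0, 0)), so 0.5 is
subtracted from each vertex on load and added back on export.  A pixel
belongs to an ROI when its center is inside or on the polygon boundary.
"""

from __future__ import annotations

import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
import tifffile
from scipy import ndimage as ndi
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

from . import ijroi

logger = logging.getLogger(__name__)

__all__ = [
    "ChannelStack",
    "LabelMap",
    "RoiSet",
    "load_channel_stack",
    "load_mask",
    "load_roi_set",
    "rois_to_labelmap",
    "labelmap_outlines",
]

ROLES = ("cell_id", "reporter1", "reporter2", "reporter3")

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class ChannelStack:
    """Ordered monochrome images for one channel, identical dimensions."""

    images: list[np.ndarray]
    bit_depth: int
    name: str = ""
    role: str = "reporter1"

    def __post_init__(self) -> None:
        if not self.images:
            raise ValueError("a channel stack needs at least one image")
        if self.bit_depth not in (8, 16, 32):
            raise ValueError(f"bit depth must be 8, 16 or 32, got {self.bit_depth}")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        shape = self.images[0].shape
        for i, img in enumerate(self.images):
            if img.ndim != 2:
                raise ValueError(f"image {i} of {self.name!r} is not a 2-D raster")
            if img.shape != shape:
                raise ValueError(
                    f"mixed dimensions in {self.name!r}: image {i} is "
                    f"{img.shape}, expected {shape}"
                )

    def __len__(self) -> int:
        return len(self.images)

    @property
    def shape(self) -> tuple[int, int]:
        return self.images[0].shape


@dataclass
class LabelMap:
    """Per-cell pixel sets: 0 = background, k > 0 = cell k (8-connected)."""

    labels: np.ndarray
    source_image_index: int = 0

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("labels must be a 2-D integer raster")
        self.labels = lab
        present = np.unique(lab)
        present = present[present > 0]
        if present.size and not np.array_equal(present, np.arange(1, present.size + 1)):
            raise ValueError("labels must be contiguous positive integers from 1")
        for k in present:
            _, n = ndi.label(lab == k, structure=_EIGHT)
            if n != 1:
                raise ValueError(f"label {k} is not a single connected component")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class RoiSet:
    """Closed cell outlines in pixel-center coordinates, order = cell order."""

    outlines: list[np.ndarray] = field(default_factory=list)
    image_index: int = 0

    def __post_init__(self) -> None:
        for i, poly in enumerate(self.outlines):
            poly = np.asarray(poly, dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise ValueError(f"outline {i} is not a polygon with >= 3 (x, y) vertices")
            self.outlines[i] = poly

    def __len__(self) -> int:
        return len(self.outlines)


def _check_monochrome(page: tifffile.TiffPage, path: str | Path) -> None:
    if page.samplesperpixel != 1 or page.photometric in (
        tifffile.PHOTOMETRIC.RGB,
        tifffile.PHOTOMETRIC.PALETTE,
        tifffile.PHOTOMETRIC.SEPARATED,  # CMYK
    ):
        raise ValueError(
            f"monochromatic input required: {path} is not a single-sample "
            "grayscale image (RGB/CMYK/palette TIFFs are rejected)"
        )


def load_channel_stack(
    paths: Sequence[str | Path] | str | Path,
    role: str = "reporter1",
    name: str | None = None,
) -> ChannelStack:
    """Load one or more TIFF files into a :class:`ChannelStack`.

    Multi-page files are unrolled in page order; several files are
    concatenated in the order given.  Lossless-compressed (ZIP/LZW) TIFFs are
    decompressed transparently by ``tifffile``.  Pixel values pass through
    bit-exact.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    images: list[np.ndarray] = []
    depths: set[int] = set()
    for path in paths:
        with tifffile.TiffFile(path) as tif:
            for page in tif.pages:
                _check_monochrome(page, path)
                arr = page.asarray()
                if arr.ndim != 2:
                    raise ValueError(f"monochromatic input required: {path}")
                depths.add(arr.dtype.itemsize * 8)
                images.append(arr)
    if not images:
        raise ValueError("no images found")
    if len(depths) > 1:
        raise ValueError(f"mixed bit depths {sorted(depths)} in one channel")
    (depth,) = depths
    if depth not in (8, 16, 32):
        raise ValueError(f"unsupported bit depth {depth}; use 8, 16 or 32-bit")
    return ChannelStack(
        images, bit_depth=depth, name=name or str(paths[0]), role=role
    )


def load_mask(path: str | Path) -> list[np.ndarray]:
    """Load a binary mask TIFF (0 = background, nonzero = foreground)."""
    stack = load_channel_stack(path, role="cell_id", name=str(path))
    return [img > 0 for img in stack.images]


def load_roi_set(path: str | Path, image_shape: tuple[int, int]) -> RoiSet:
    """Read an ImageJ ``.roi`` file or RoiSet zip into pixel-center coords.

    ROI (archive) order is preserved — it defines cell numbering.
    """
    path = Path(path)
    if zipfile.is_zipfile(path):
        raw = ijroi.read_roi_zip(path)
    else:
        raw = [ijroi.read_roi(path)]
    if not raw:
        raise ValueError(f"no ROIs found in {path}")
    outlines = []
    for r in raw:
        if r.n < 3:
            raise ValueError(f"ROI {r.name!r} has fewer than 3 vertices")
        # ImageJ corner lattice -> pixel-center coordinates
        outlines.append(np.column_stack([np.asarray(r.x) - 0.5, np.asarray(r.y) - 0.5]))
    return RoiSet(outlines)


def rois_to_labelmap(rois: RoiSet, shape: tuple[int, int]) -> LabelMap:
    """Rasterize ROI outlines into a label map.

    A pixel gets label ``k`` when its center is inside or on the boundary of
    outline ``k``; where outlines overlap, the later ROI wins.  Outlines
    entirely outside the frame are dropped with a warning.
    """
    h, w = shape
    labels = np.zeros(shape, dtype=np.int32)
    next_label = 0
    for i, poly_xy in enumerate(rois.outlines):
        poly = Polygon(poly_xy)
        if not poly.is_valid:
            poly = poly.buffer(0)
        minx, miny, maxx, maxy = poly.bounds
        c0 = max(0, int(np.ceil(minx)))
        c1 = min(w - 1, int(np.floor(maxx)))
        r0 = max(0, int(np.ceil(miny)))
        r1 = min(h - 1, int(np.floor(maxy)))
        if c0 > c1 or r0 > r1:
            logger.warning("ROI %d lies outside the image and was dropped", i + 1)
            continue
        cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
        shapely.prepare(poly)
        inside = shapely.intersects_xy(poly, cols.ravel(), rows.ravel())
        if not inside.any():
            logger.warning("ROI %d covers no pixel centers and was dropped", i + 1)
            continue
        next_label += 1
        sub = labels[r0 : r1 + 1, c0 : c1 + 1]
        sub[inside.reshape(sub.shape)] = next_label
    # later-ROI overwrites can empty an earlier label: renumber contiguously
    present = np.unique(labels)
    present = present[present > 0]
    remap = np.zeros(next_label + 1, dtype=np.int32)
    remap[present] = np.arange(1, present.size + 1)
    return LabelMap(remap[labels])


def labelmap_outlines(labelmap: LabelMap) -> RoiSet:
    """Trace each object's outer boundary along pixel edges.

    Returns one closed polygon per label, in label order, in pixel-center
    coordinates (vertices on the half-integer corner lattice).  Rasterizing
    these outlines with :func:`rois_to_labelmap` reproduces the original
    pixel sets for hole-free objects; holes are filled and, for objects whose
    pixel squares touch only at corners, the largest part is traced.
    """
    outlines: list[np.ndarray] = []
    lab = labelmap.labels
    for k in range(1, labelmap.n_objects + 1):
        rr, cc = np.nonzero(lab == k)
        squares = [box(c - 0.5, r - 0.5, c + 0.5, r + 0.5) for r, c in zip(rr, cc)]
        union = unary_union(squares)
        if union.geom_type == "MultiPolygon":
            logger.warning(
                "object %d splits into corner-touching parts; tracing the largest", k
            )
            union = max(union.geoms, key=lambda g: g.area)
        coords = np.asarray(union.exterior.coords[:-1], dtype=float)
        outlines.append(coords)
    return RoiSet(outlines, image_index=labelmap.source_image_index)
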