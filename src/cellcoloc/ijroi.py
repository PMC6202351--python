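"""Minimal reader/writer for the ImageJ ROI file format (.roi, RoiSet.zip).

Only the subset needed for cell outlines is supported: polygon, rectangle,
freehand and traced ROIs with 16-bit integer vertex coordinates.  Coordinates
returned and accepted here are in ImageJ's convention (x right, y down,
origin at the top-left *corner* of the top-left pixel); conversion to the
package's pixel-center convention happens in :mod:`cellcoloc.io`.

Format reference: the header layout of ImageJ's ``RoiDecoder``/``RoiEncoder``
(magic ``Iout``, big-endian shorts for bounds and vertex counts, vertex
coordinates stored relative to the bounding box).
"""

from __future__ import annotations

import struct
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import BinaryIO

__all__ = ["IJRoi", "read_roi", "read_roi_zip", "write_roi", "write_roi_zip"]

_MAGIC = b"Iout"
_VERSION = 227

# ImageJ ROI type codes
POLYGON = 0
RECT = 1
OVAL = 2
LINE = 3
FREELINE = 4
POLYLINE = 5
NO_ROI = 6
FREEHAND = 7
TRACED = 8

_POLYGONAL = {POLYGON, FREEHAND, TRACED}

_OPT_SUBPIXEL = 128


@dataclass
class IJRoi:
    """A closed-outline ROI with vertices in ImageJ corner coordinates."""

    x: list[float]
    y: list[float]
    roi_type: int = POLYGON
    name: str | None = None

    @property
    def n(self) -> int:
        return len(self.x)


def _parse(buf: bytes, name: str | None = None) -> IJRoi:
    if len(buf) < 64 or buf[:4] != _MAGIC:
        raise ValueError(f"not an ImageJ ROI file: {name or '<bytes>'}")
    roi_type = buf[6]
    top, left, bottom, right = struct.unpack(">4h", buf[8:16])
    n_coords = struct.unpack(">H", buf[16:18])[0]
    options = struct.unpack(">H", buf[50:52])[0]

    if roi_type == RECT:
        xs = [left, right, right, left]
        ys = [top, top, bottom, bottom]
        return IJRoi([float(v) for v in xs], [float(v) for v in ys], RECT, name)
    if roi_type not in _POLYGONAL:
        raise ValueError(
            f"unsupported ROI type {roi_type} in {name or '<bytes>'}; "
            "only polygon, rectangle, freehand and traced ROIs are supported"
        )
    if n_coords == 0:
        raise ValueError(f"ROI {name or '<bytes>'} has no vertices")

    if options & _OPT_SUBPIXEL and len(buf) >= 64 + 4 * n_coords + 8 * n_coords:
        off = 64 + 4 * n_coords
        xs = struct.unpack(f">{n_coords}f", buf[off : off + 4 * n_coords])
        off += 4 * n_coords
        ys = struct.unpack(f">{n_coords}f", buf[off : off + 4 * n_coords])
        return IJRoi(list(xs), list(ys), roi_type, name)

    off = 64
    rel_x = struct.unpack(f">{n_coords}h", buf[off : off + 2 * n_coords])
    off += 2 * n_coords
    rel_y = struct.unpack(f">{n_coords}h", buf[off : off + 2 * n_coords])
    return IJRoi(
        [float(left + v) for v in rel_x],
        [float(top + v) for v in rel_y],
        roi_type,
        name,
    )


def read_roi(path: str | Path | BinaryIO) -> IJRoi:
    """Read a single ``.roi`` file."""
    if hasattr(path, "read"):
        return _parse(path.read())
    p = Path(path)
    return _parse(p.read_bytes(), p.stem)


def read_roi_zip(path: str | Path) -> list[IJRoi]:
    """Read all ``.roi`` entries of a RoiSet zip, in archive order."""
    rois: list[IJRoi] = []
    with zipfile.ZipFile(path) as zf:
        for info in zf.infolist():
            if not info.filename.lower().endswith(".roi"):
                continue
            rois.append(_parse(zf.read(info), Path(info.filename).stem))
    return rois


def _encode(roi: IJRoi) -> bytes:
    xs = [int(round(v)) for v in roi.x]
    ys = [int(round(v)) for v in roi.y]
    left, top = min(xs), min(ys)
    right, bottom = max(xs), max(ys)
    n = len(xs)
    header = bytearray(64)
    header[0:4] = _MAGIC
    struct.pack_into(">h", header, 4, _VERSION)
    header[6] = roi.roi_type if roi.roi_type in _POLYGONAL else POLYGON
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">H", header, 16, n)
    body = struct.pack(f">{n}h", *(x - left for x in xs))
    body += struct.pack(f">{n}h", *(y - top for y in ys))
    return bytes(header) + body


def write_roi(roi: IJRoi, path: str | Path) -> None:
    Path(path).write_bytes(_encode(roi))


def write_roi_zip(rois: list[IJRoi], path: str | Path) -> None:
    """Write a RoiSet zip; entry names follow ImageJ's ``NNNN-....roi`` habit."""
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for i, roi in enumerate(rois, start=1):
            name = roi.name or f"{i:04d}"
            zf.writestr(f"{name}.roi", _encode(roi))
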