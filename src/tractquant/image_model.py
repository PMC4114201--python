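"""Data model and I/O for image sections, ROIs, and tabular outputs.

Coordinate convention (used throughout the package): 0-based pixel indices,
x increases rightward (columns), y increases downward (rows), and the centre
of pixel ``(x, y)`` sits at the continuous point ``(x + 0.5, y + 0.5)``.
ROI JSON files carry this convention explicitly in their ``convention``
field so that files are self-describing.

Images are handled at 8-bit working depth; higher acquisition depths (12 or
16 bit) are reduced by a pure bit shift (:func:`convert_to_8bit`), not by
contrast stretching.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "ImageSection",
    "ImageStack",
    "PolygonROI",
    "BoxROI",
    "BinaryMask",
    "ValidationError",
    "convert_to_8bit",
    "rasterize",
    "read_section",
    "write_section",
    "load_roi_json",
    "save_roi_json",
    "read_imagej_roi",
    "write_quant_csv",
    "QUANT_CSV_COLUMNS",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ImageSection:
    """One physical tissue section with one or more registered channels.

    Parameters
    ----------
    channels
        Mapping of channel name (e.g. ``"TRITC"``, ``"Nissl"``) to a 2D
        ``uint8`` intensity array of shape ``(rows, cols)``.
    pixel_size_um
        Micrometres per pixel, isotropic in x and y.
    thickness_um
        Physical section thickness in micrometres.
    section_index
        Integer position along the antero-posterior axis.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    thickness_um: float
    section_index: int = 0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError("section must have at least one channel")
        shapes = {name: np.asarray(a).shape for name, a in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(s != first for s in shapes.values()):
            raise ValidationError(f"channel dimensions differ: {shapes}")
        if len(first) != 2:
            raise ValidationError("channels must be 2D (rows, cols)")
        for name, arr in self.channels.items():
            arr = np.asarray(arr)
            if arr.dtype != np.uint8:
                if np.any(arr < 0) or np.any(arr > 255):
                    raise ValidationError(
                        f"channel {name!r} has intensities outside [0, 255]; "
                        "use convert_to_8bit() first"
                    )
                arr = arr.astype(np.uint8)
            self.channels[name] = arr
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be positive")
        if not self.thickness_um > 0:
            raise ValidationError("thickness_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class ImageStack:
    """A two-or-more-channel 3D stack: channel name -> array of (z, y, x)."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 1.0
    z_step_um: float = 1.0

    def __post_init__(self) -> None:
        shapes = {n: np.asarray(a).shape for n, a in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(s != first for s in shapes.values()) or len(first) != 3:
            raise ValidationError(f"stack channels must share one 3D shape, got {shapes}")
        for name, arr in self.channels.items():
            self.channels[name] = np.asarray(arr).astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class PolygonROI:
    """An experimenter-traced closed outline in pixel coordinates.

    ``vertices`` is an ordered ``(n, 2)`` array of (x, y) points; the polygon
    is implicitly closed.  Must be simple (non-self-intersecting).
    """

    vertices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValidationError(
                f"polygon needs >= 3 (x, y) vertices, got shape {v.shape}"
            )
        poly = _ShapelyPolygon(v)
        if not poly.is_valid or poly.area == 0:
            raise ValidationError(
                f"polygon {self.label!r} is not simple (self-intersecting or degenerate)"
            )
        self.vertices = v

    def to_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)

    @property
    def area(self) -> float:
        return self.to_shapely().area


@dataclass
class BoxROI:
    """Axis-aligned rectangle with half-open integer bounds.

    ``left <= x < right`` and ``top <= y < bottom``.  Each side can be moved
    independently, which is what the expanding spillover-box search does.
    """

    left: int
    right: int
    top: int
    bottom: int

    def __post_init__(self) -> None:
        if not (self.right > self.left and self.bottom > self.top):
            raise ValidationError(
                f"degenerate box: ({self.left}, {self.right}, {self.top}, {self.bottom})"
            )

    @property
    def width(self) -> int:
        return self.right - self.left

    @property
    def height(self) -> int:
        return self.bottom - self.top

    @property
    def area_px(self) -> int:
        return self.width * self.height

    def clipped(self, shape: tuple[int, int]) -> "BoxROI":
        rows, cols = shape
        return BoxROI(
            left=max(self.left, 0),
            right=min(self.right, cols),
            top=max(self.top, 0),
            bottom=min(self.bottom, rows),
        )

    def slices(self) -> tuple[slice, slice]:
        """(row, col) slices for numpy indexing."""
        return slice(self.top, self.bottom), slice(self.left, self.right)

    def overlaps(self, other: "BoxROI") -> bool:
        return not (
            self.right <= other.left
            or other.right <= self.left
            or self.bottom <= other.top
            or other.bottom <= self.top
        )


@dataclass
class BinaryMask:
    """Boolean pixel mask congruent with an :class:`ImageSection`."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValidationError("mask must be 2D")

    @property
    def area_px(self) -> int:
        return int(self.grid.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def convert_to_8bit(section_raw: np.ndarray, bit_depth: int) -> np.ndarray:
    """Reduce a raw integer image of declared bit depth to 8-bit.

    The mapping is a pure bit shift: integer division by ``2**(depth - 8)``.
    No contrast stretching is applied, so relative intensities (and therefore
    thresholds expressed in 8-bit units) are depth-independent up to
    quantisation.

    Parameters
    ----------
    section_raw
        Integer array with values in ``[0, 2**bit_depth - 1]``.
    bit_depth
        One of 8, 12 or 16.
    """
    if bit_depth not in (8, 12, 16):
        raise ValidationError(f"unsupported bit depth {bit_depth}; expected 8, 12 or 16")
    arr = np.asarray(section_raw)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValidationError("raw image must be an integer array")
    limit = 2**bit_depth - 1
    bad = (arr < 0) | (arr > limit)
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValidationError(
            f"pixel {idx} has value {int(arr[idx])}, outside [0, {limit}] "
            f"for declared {bit_depth}-bit depth"
        )
    if bit_depth == 8:
        return arr.astype(np.uint8)
    return (arr // (2 ** (bit_depth - 8))).astype(np.uint8)


def rasterize(roi: PolygonROI, shape: tuple[int, int]) -> BinaryMask:
    """Rasterize a polygon ROI onto a pixel grid.

    A pixel is inside iff its centre ``(x + 0.5, y + 0.5)`` lies strictly
    inside the polygon; containment follows the even-odd rule as implemented
    by shapely, which resolves boundary-grazing centres deterministically.
    """
    rows, cols = int(shape[0]), int(shape[1])
    if rows <= 0 or cols <= 0:
        raise ValidationError(f"invalid raster shape {shape}")
    poly = roi.to_shapely()
    grid = np.zeros((rows, cols), dtype=bool)
    # Only test pixel centres within the polygon bounding box.
    minx, miny, maxx, maxy = poly.bounds
    x0 = max(int(np.floor(minx - 0.5)), 0)
    x1 = min(int(np.ceil(maxx + 0.5)), cols)
    y0 = max(int(np.floor(miny - 0.5)), 0)
    y1 = min(int(np.ceil(maxy + 0.5)), rows)
    if x1 > x0 and y1 > y0:
        xs = np.arange(x0, x1) + 0.5
        ys = np.arange(y0, y1) + 0.5
        xx, yy = np.meshgrid(xs, ys)
        inside = shapely.contains_xy(poly, xx.ravel(), yy.ravel())
        grid[y0:y1, x0:x1] = inside.reshape(y1 - y0, x1 - x0)
    mask = BinaryMask(grid)
    if mask.area_px == 0:
        warnings.warn(
            f"polygon {roi.label!r} rasterizes to an empty mask on shape {shape}",
            stacklevel=2,
        )
    return mask


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_TIFF_META_KEY = "tractquant"


def write_section(path: str | Path, section: ImageSection) -> None:
    """Write an :class:`ImageSection` as a multi-page TIFF.

    Channels become pages in insertion order; names and physical metadata go
    into the image description as JSON so a round trip is lossless.
    """
    names = list(section.channels)
    data = np.stack([section.channels[n] for n in names])
    meta = {
        "channel_names": names,
        "pixel_size_um": section.pixel_size_um,
        "thickness_um": section.thickness_um,
        "section_index": section.section_index,
    }
    tifffile.imwrite(path, data, description=json.dumps({_TIFF_META_KEY: meta}))


def read_section(
    path: str | Path,
    channel_names: Sequence[str] | None = None,
    pixel_size_um: float | None = None,
    thickness_um: float | None = None,
    section_index: int | None = None,
) -> ImageSection:
    """Read a multi-page/multi-sample TIFF into an :class:`ImageSection`.

    Files written by :func:`write_section` are self-describing; for foreign
    TIFFs, supply ``channel_names`` (and physical metadata) explicitly.
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or ""
    meta: dict = {}
    try:
        meta = json.loads(desc).get(_TIFF_META_KEY, {})
    except (json.JSONDecodeError, AttributeError):
        pass

    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValidationError(f"expected a 2D or 3D TIFF, got shape {data.shape}")

    names = list(channel_names) if channel_names is not None else meta.get("channel_names")
    if names is None:
        raise ValidationError(
            "TIFF carries no channel-name metadata; pass channel_names explicitly"
        )
    if len(names) != data.shape[0]:
        raise ValidationError(
            f"config names {len(names)} channels ({names}) but TIFF holds "
            f"{data.shape[0]} page(s)"
        )
    return ImageSection(
        channels={n: data[i] for i, n in enumerate(names)},
        pixel_size_um=pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um", 1.0),
        thickness_um=thickness_um if thickness_um is not None else meta.get("thickness_um", 1.0),
        section_index=section_index if section_index is not None else meta.get("section_index", 0),
    )


_ROI_CONVENTION = "0-based,center"


def save_roi_json(path: str | Path, roi: PolygonROI) -> None:
    payload = {
        "label": roi.label,
        "vertices": [[float(x), float(y)] for x, y in roi.vertices],
        "convention": _ROI_CONVENTION,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_roi_json(path: str | Path) -> PolygonROI:
    payload = json.loads(Path(path).read_text())
    conv = payload.get("convention", _ROI_CONVENTION)
    if conv != _ROI_CONVENTION:
        raise ValidationError(f"unsupported ROI coordinate convention {conv!r}")
    return PolygonROI(vertices=np.asarray(payload["vertices"], float), label=payload.get("label", ""))


# ImageJ .roi record types that describe a closed outline we can use.
_IJ_POLYGON_TYPES = {0: "polygon", 7: "freehand", 8: "traced"}


def read_imagej_roi(path: str | Path) -> PolygonROI:
    """Import a polygon-type ImageJ ``.roi`` binary record.

    Supports the polygon, freehand and traced outline record types; integer
    vertex coordinates are shifted to pixel centres under this package's
    half-integer-centre convention.
    """
    buf = Path(path).read_bytes()
    if buf[:4] != b"Iout":
        raise ValidationError(f"{path}: not an ImageJ .roi file (bad magic)")
    roi_type = buf[6]
    if roi_type not in _IJ_POLYGON_TYPES:
        raise ValidationError(
            f"{path}: .roi record type {roi_type} is not a polygon outline"
        )
    top, left, _bottom, _right, n = struct.unpack(">hhhhh", buf[8:18])
    if n < 3:
        raise ValidationError(f"{path}: outline has only {n} vertices")
    xs = np.frombuffer(buf, dtype=">i2", count=n, offset=64).astype(float)
    ys = np.frombuffer(buf, dtype=">i2", count=n, offset=64 + 2 * n).astype(float)
    verts = np.column_stack([xs + left, ys + top])
    name = Path(path).stem
    return PolygonROI(vertices=verts, label=name)


QUANT_CSV_COLUMNS = [
    "section_index",
    "roi_area_px",
    "threshold",
    "labeled_px_in_roi",
    "spillover_px",
    "box_left",
    "box_right",
    "box_top",
    "box_bottom",
]


def write_quant_csv(path: str | Path, quants: Sequence) -> pd.DataFrame:
    """Write per-section quantification rows to CSV (one row per section).

    ``quants`` is a sequence of ``SectionQuant`` results; an empty sequence
    yields a header-only file.  Returns the DataFrame written.
    """
    rows = []
    for q in quants:
        rows.append(
            {
                "section_index": q.section_index,
                "roi_area_px": q.roi_area_px,
                "threshold": q.threshold_spec.threshold,
                "labeled_px_in_roi": q.labeled_px_in_roi,
                "spillover_px": q.spillover_px,
                "box_left": q.final_box.left,
                "box_right": q.final_box.right,
                "box_top": q.final_box.top,
                "box_bottom": q.final_box.bottom,
            }
        )
    df = pd.DataFrame(rows, columns=QUANT_CSV_COLUMNS)
    df.to_csv(path, index=False)
    return df
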