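"""Frame and ROI input/output plus polygon rasterization.

Coordinate convention: 0-based ``(row, col)``, with the pixel center of
pixel ``(i, j)`` at exactly ``(i, j)``.  A pixel belongs to a polygon iff
its center is inside under the even-odd rule; centers lying exactly on a
polygon edge are included.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

ROI_LABELS = ("myocardial", "pericardial")

#: default lower bound on rasterized ROI size; a tiny ROI makes the
#: 25th percentile meaningless.
MIN_ROI_PIXELS = 32

_EDGE_EPS = 1e-9


class BitDepthError(ValueError):
    """Source image is not 8-bit and rescaling was not requested."""


class RoiError(ValueError):
    """ROI is malformed, degenerate or incompatible with the frame."""


@dataclass(frozen=True)
class EchoFrame:
    """A single 8-bit grayscale B-mode frame."""

    pixels: np.ndarray
    frame_index: int = 0
    source_id: str = ""
    bit_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if self.bit_depth != 8:
            raise BitDepthError(f"bit depth must be 8, got {self.bit_depth}")
        if px.shape[0] < 16 or px.shape[1] < 16:
            raise ValueError(f"frame must be at least 16x16, got {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("pixel intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class RegionOfInterest:
    """A labeled simple polygon in pixel coordinates.

    ``vertices`` is an ordered list of ``(row, col)`` pairs; the polygon is
    implicitly closed (last vertex joins back to the first).
    """

    label: str
    vertices: tuple = ()
    closed: bool = True

    def __post_init__(self) -> None:
        if self.label not in ROI_LABELS:
            raise RoiError(f"unknown label {self.label!r}; expected one of {ROI_LABELS}")
        verts = tuple((float(r), float(c)) for r, c in self.vertices)
        if len(verts) < 3:
            raise RoiError("polygon needs >=3 vertices")
        object.__setattr__(self, "vertices", verts)
        if abs(_shoelace_area(verts)) < _EDGE_EPS:
            raise RoiError("degenerate polygon (zero area)")
        if not _is_simple(verts):
            raise RoiError("polygon is self-intersecting")

    def translated(self, drow: float, dcol: float) -> "RegionOfInterest":
        return RegionOfInterest(
            label=self.label,
            vertices=tuple((r + drow, c + dcol) for r, c in self.vertices),
            closed=self.closed,
        )


@dataclass(frozen=True)
class PixelSample:
    """Multiset of intensities gathered from one ROI on one frame."""

    intensities: np.ndarray
    roi_label: str
    source_id: str = ""
    frame_index: int = 0

    def __post_init__(self) -> None:
        vals = np.asarray(self.intensities).ravel()
        if vals.size and (vals.min() < 0 or vals.max() > 255):
            raise ValueError("intensities must lie in [0, 255]")
        object.__setattr__(self, "intensities", vals.astype(np.int64))

    @property
    def n(self) -> int:
        return int(self.intensities.size)


def _shoelace_area(verts: Sequence[tuple]) -> float:
    a = np.asarray(verts, dtype=float)
    r, c = a[:, 0], a[:, 1]
    return 0.5 * float(np.sum(c * np.roll(r, -1) - np.roll(c, -1) * r))


def _orient(p, q, r) -> float:
    return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])


def _segments_properly_intersect(a, b, c, d) -> bool:
    d1 = _orient(c, d, a)
    d2 = _orient(c, d, b)
    d3 = _orient(a, b, c)
    d4 = _orient(a, b, d)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)) and all(
        abs(x) > _EDGE_EPS for x in (d1, d2, d3, d4)
    )


def _is_simple(verts: Sequence[tuple]) -> bool:
    k = len(verts)
    edges = [(verts[i], verts[(i + 1) % k]) for i in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            if j == i + 1 or (i == 0 and j == k - 1):
                continue  # adjacent edges share an endpoint by construction
            if _segments_properly_intersect(*edges[i], *edges[j]):
                return False
    return True


def _point_on_edge(py: float, px: float, verts: Sequence[tuple]) -> bool:
    k = len(verts)
    for i in range(k):
        y1, x1 = verts[i]
        y2, x2 = verts[(i + 1) % k]
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        if abs(cross) > _EDGE_EPS * max(1.0, abs(x2 - x1) + abs(y2 - y1)):
            continue
        if (min(y1, y2) - _EDGE_EPS <= py <= max(y1, y2) + _EDGE_EPS) and (
            min(x1, x2) - _EDGE_EPS <= px <= max(x1, x2) + _EDGE_EPS
        ):
            return True
    return False


def point_in_polygon(py: float, px: float, verts: Sequence[tuple]) -> bool:
    """Even-odd test for a single point; on-edge points count as inside."""
    if _point_on_edge(py, px, verts):
        return True
    inside = False
    k = len(verts)
    for i in range(k):
        y1, x1 = verts[i]
        y2, x2 = verts[(i + 1) % k]
        if (y1 > py) != (y2 > py):
            x_at = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_at:
                inside = not inside
    return inside


def rasterize_roi(
    roi: RegionOfInterest,
    frame: EchoFrame,
    min_pixels: int = MIN_ROI_PIXELS,
) -> np.ndarray:
    """Boolean mask of ``frame`` shape selecting pixels whose centers lie
    inside (or exactly on the boundary of) the ROI polygon."""
    verts = np.asarray(roi.vertices, dtype=float)
    if (
        verts[:, 0].min() < 0
        or verts[:, 1].min() < 0
        or verts[:, 0].max() > frame.height - 1
        or verts[:, 1].max() > frame.width - 1
    ):
        raise RoiError("ROI vertices fall outside frame bounds")

    r_lo = max(0, int(np.floor(verts[:, 0].min())))
    r_hi = min(frame.height - 1, int(np.ceil(verts[:, 0].max())))
    c_lo = max(0, int(np.floor(verts[:, 1].min())))
    c_hi = min(frame.width - 1, int(np.ceil(verts[:, 1].max())))

    rows = np.arange(r_lo, r_hi + 1, dtype=float)
    cols = np.arange(c_lo, c_hi + 1, dtype=float)
    py, px = np.meshgrid(rows, cols, indexing="ij")
    inside = np.zeros(py.shape, dtype=bool)
    on_edge = np.zeros(py.shape, dtype=bool)

    k = len(roi.vertices)
    for i in range(k):
        y1, x1 = roi.vertices[i]
        y2, x2 = roi.vertices[(i + 1) % k]
        crosses = (y1 > py) != (y2 > py)
        if np.any(crosses):
            with np.errstate(divide="ignore", invalid="ignore"):
                x_at = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            inside ^= crosses & (px < x_at)
        # on-edge detection for this segment
        seg_scale = max(1.0, abs(x2 - x1) + abs(y2 - y1))
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        bb = (
            (py >= min(y1, y2) - _EDGE_EPS)
            & (py <= max(y1, y2) + _EDGE_EPS)
            & (px >= min(x1, x2) - _EDGE_EPS)
            & (px <= max(x1, x2) + _EDGE_EPS)
        )
        on_edge |= (np.abs(cross) <= _EDGE_EPS * seg_scale) & bb

    sub = inside | on_edge
    mask = np.zeros((frame.height, frame.width), dtype=bool)
    mask[r_lo : r_hi + 1, c_lo : c_hi + 1] = sub
    count = int(mask.sum())
    if count < min_pixels:
        raise RoiError(f"ROI rasterizes to {count} pixels; minimum is {min_pixels}")
    return mask


def extract_pixels(
    frame: EchoFrame,
    roi: RegionOfInterest,
    min_pixels: int = MIN_ROI_PIXELS,
) -> PixelSample:
    """Gather the intensity multiset of all ROI pixels on ``frame``."""
    mask = rasterize_roi(roi, frame, min_pixels=min_pixels)
    return PixelSample(
        intensities=frame.pixels[mask],
        roi_label=roi.label,
        source_id=frame.source_id,
        frame_index=frame.frame_index,
    )


# ---------------------------------------------------------------------------
# file I/O


def _to_luma(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            luma = 0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
            return np.rint(luma).astype(arr.dtype)
        arr = arr[:, :, 0]
    return arr


def _coerce_8bit(arr: np.ndarray, rescale: bool, source: str) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr
    if not rescale:
        raise BitDepthError(
            f"{source}: bit depth is not 8 (dtype {arr.dtype}); pass rescale=True to min-max rescale"
        )
    arr = arr.astype(np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi > lo:
        arr = (arr - lo) / (hi - lo) * 255.0
    else:
        arr = np.zeros_like(arr)
    warnings.warn(f"{source}: non-8-bit source min-max rescaled to [0, 255]", stacklevel=2)
    return np.rint(arr).astype(np.uint8)


def _read_dicom(path: Path, frame_index: int, rescale: bool) -> EchoFrame:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - depends on optional extra
        raise ImportError(
            "reading DICOM requires the optional 'pydicom' dependency "
            "(pip install echostruct[dicom])"
        ) from exc
    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array
    n_frames = int(getattr(ds, "NumberOfFrames", 1) or 1)
    if n_frames > 1:
        if not 0 <= frame_index < n_frames:
            raise IndexError(f"frame index {frame_index} out of range [0, {n_frames})")
        arr = arr[frame_index]
    elif frame_index != 0:
        raise IndexError(f"frame index {frame_index} out of range for single-frame source")
    arr = _to_luma(np.asarray(arr))
    arr = _coerce_8bit(arr, rescale, str(path))
    return EchoFrame(pixels=arr, frame_index=frame_index, source_id=str(path))


def read_frame(path, frame_index: int = 0, rescale: bool = False) -> EchoFrame:
    """Read one 8-bit grayscale frame from a DICOM, PNG or JPEG source.

    Color sources are converted to luma grayscale.  Non-8-bit sources are
    rejected unless ``rescale`` is set, in which case they are min-max
    rescaled to [0, 255] with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        return _read_dicom(path, frame_index, rescale)
    if suffix not in (".png", ".jpg", ".jpeg"):
        raise ValueError(f"unsupported image format {suffix!r}; expected DICOM, PNG or JPEG")
    if frame_index != 0:
        raise IndexError(f"frame index {frame_index} out of range for single-frame source")
    arr = np.asarray(iio.imread(path))
    arr = _to_luma(arr)
    arr = _coerce_8bit(arr, rescale, str(path))
    return EchoFrame(pixels=arr, frame_index=0, source_id=str(path))


def write_frame(frame: EchoFrame, path) -> None:
    """Write a frame as 8-bit grayscale PNG (lossless)."""
    iio.imwrite(Path(path), frame.pixels)


def write_mask(mask: np.ndarray, path) -> None:
    """Export a boolean mask as a 0/255 PNG."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_roi_file(path) -> list:
    """Read ROI polygons from JSON: a list of ``{"label", "vertices"}`` objects."""
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise RoiError("ROI file must contain a JSON list of ROI objects")
    rois = []
    for item in data:
        if not isinstance(item, dict) or "label" not in item or "vertices" not in item:
            raise RoiError("each ROI object needs 'label' and 'vertices' keys")
        rois.append(RegionOfInterest(label=item["label"], vertices=[tuple(v) for v in item["vertices"]]))
    return rois


def write_roi_file(rois: Sequence[RegionOfInterest], path) -> None:
    data = [
        {"label": roi.label, "vertices": [[r, c] for r, c in roi.vertices]}
        for roi in rois
    ]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
        fh.write("\n")
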