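"""Reading and writing AFM height maps and CNO detection annotations.

Conventions pinned repo-wide:

* coordinates are 0-based pixels, ``x`` = column, ``y`` = row, origin at the
  top-left; bounding boxes are half-open on the max edge;
* height maps are stored either as whitespace-delimited matrix text or as
  single-channel TIFF, with a ``<basename>.meta.yaml`` sidecar carrying
  ``pixel_size_nm`` and free-form provenance;
* detections are interchanged in the YOLO text convention
  (``class cx cy w h [conf]``, all normalized to [0, 1]).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import tifffile
import yaml

from .exceptions import DataError, FormatError, ParameterError

__all__ = [
    "DEFAULT_PIXEL_SIZE_NM",
    "HeightMap",
    "BoundingBox",
    "Detection",
    "DetectionSet",
    "read_heightmap",
    "write_heightmap",
    "read_detections_yolo",
    "write_detections_yolo",
    "sidecar_path",
]

logger = logging.getLogger(__name__)

#: 512 px spanning a 20 x 20 um^2 scan: 20000 nm / 512 px.
DEFAULT_PIXEL_SIZE_NM = 20000.0 / 512.0

_MIN_SIDE = 8


@dataclass
class HeightMap:
    """A 2D grid of surface heights in nanometres with physical pixel size."""

    heights: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise DataError(f"height grid must be 2D, got ndim={self.heights.ndim}")
        if self.heights.shape[0] < _MIN_SIDE or self.heights.shape[1] < _MIN_SIDE:
            raise DataError(
                f"height grid must be at least {_MIN_SIDE}x{_MIN_SIDE}, got {self.heights.shape}"
            )
        if not np.all(np.isfinite(self.heights)):
            raise DataError("height grid contains non-finite values")
        if not (np.isfinite(self.pixel_size_nm) and self.pixel_size_nm > 0):
            raise ParameterError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")

    @property
    def n_rows(self) -> int:
        return self.heights.shape[0]

    @property
    def n_cols(self) -> int:
        return self.heights.shape[1]

    @property
    def area_um2(self) -> float:
        """Imaged area in square micrometres."""
        px_um = self.pixel_size_nm / 1000.0
        return self.n_rows * self.n_cols * px_um * px_um


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in pixel coordinates, half-open on the max edge."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        vals = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(np.isfinite(v) for v in vals):
            raise DataError(f"box coordinates must be finite, got {vals}")
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise DataError(f"degenerate box {vals}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))


@dataclass(frozen=True)
class Detection:
    """One detected (or annotated) CNO: a box plus an optional confidence."""

    box: BoundingBox
    score: float | None = None

    def __post_init__(self) -> None:
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise DataError(f"score must be in [0, 1], got {self.score}")

    @property
    def centroid_x(self) -> float:
        return self.box.center[0]

    @property
    def centroid_y(self) -> float:
        return self.box.center[1]


@dataclass
class DetectionSet:
    """An ordered collection of detections tied to an image's pixel dimensions."""

    detections: list[Detection]
    image_w: int
    image_h: int
    source: str = "ground_truth"  # ground_truth | classical | external

    def __post_init__(self) -> None:
        if self.image_w <= 0 or self.image_h <= 0:
            raise ParameterError("image dimensions must be positive")
        for det in self.detections:
            b = det.box
            if b.x_min < 0 or b.y_min < 0 or b.x_max > self.image_w or b.y_max > self.image_h:
                raise DataError(
                    f"box {b} outside image bounds {self.image_w}x{self.image_h}"
                )

    def __len__(self) -> int:
        return len(self.detections)

    def __iter__(self) -> Iterator[Detection]:
        return iter(self.detections)

    @property
    def scores(self) -> np.ndarray | None:
        if any(d.score is None for d in self.detections):
            return None
        return np.array([d.score for d in self.detections], dtype=float)

    def centroids(self) -> np.ndarray:
        """(n, 2) array of (x, y) box centers."""
        if not self.detections:
            return np.empty((0, 2), dtype=float)
        return np.array([[d.centroid_x, d.centroid_y] for d in self.detections])


def sidecar_path(path: str | Path) -> Path:
    """Metadata sidecar companion of a height-map file: same basename, ``.meta.yaml``."""
    p = Path(path)
    return p.with_name(p.stem + ".meta.yaml")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("matrix_txt", "tiff"):
            raise ParameterError(f"unknown height-map format {fmt!r}")
        return fmt
    return "tiff" if path.suffix.lower() in (".tif", ".tiff") else "matrix_txt"


def read_heightmap(path: str | Path, format: str | None = None) -> HeightMap:
    """Read a height map from matrix text or single-channel TIFF.

    A ``.meta.yaml`` sidecar (same basename) may supply ``pixel_size_nm``,
    an optional ``nm_per_count`` scale for integer TIFFs, and free-form
    provenance keys. Without a sidecar the pixel size defaults to
    39.0625 nm (512 px over 20 um) with a logged warning.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "matrix_txt":
        try:
            arr = np.loadtxt(path, dtype=float, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: not a rectangular numeric matrix ({exc})") from exc
    else:
        arr = tifffile.imread(path)
        if arr.ndim != 2:
            raise FormatError(f"{path}: expected single-channel TIFF, got shape {arr.shape}")
        arr = np.asarray(arr)

    meta: dict = {}
    pixel_size_nm = None
    sp = sidecar_path(path)
    if sp.exists():
        loaded = yaml.safe_load(sp.read_text()) or {}
        if not isinstance(loaded, dict):
            raise FormatError(f"{sp}: sidecar must be a key/value mapping")
        meta = dict(loaded)
        pixel_size_nm = meta.pop("pixel_size_nm", None)
        scale = meta.pop("nm_per_count", None)
        if scale is not None:
            arr = arr.astype(float) * float(scale)
    if pixel_size_nm is None:
        pixel_size_nm = DEFAULT_PIXEL_SIZE_NM
        logger.warning(
            "%s: no pixel_size_nm in sidecar; assuming default %.4f nm/px", path, pixel_size_nm
        )

    arr = np.asarray(arr, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DataError(f"{path}: non-finite height values")
    return HeightMap(heights=arr, pixel_size_nm=float(pixel_size_nm), meta=meta)


def write_heightmap(hm: HeightMap, path: str | Path, format: str | None = None) -> Path:
    """Write a height map (plus its metadata sidecar); returns the data path."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "matrix_txt":
        np.savetxt(path, hm.heights, fmt="%.8g")
    else:
        tifffile.imwrite(path, hm.heights.astype(np.float32))
    payload = {"pixel_size_nm": float(hm.pixel_size_nm), **hm.meta}
    sidecar_path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def _clip_box(x_min: float, y_min: float, x_max: float, y_max: float,
              w: int, h: int) -> BoundingBox:
    return BoundingBox(
        x_min=max(0.0, min(x_min, w)),
        y_min=max(0.0, min(y_min, h)),
        x_max=max(0.0, min(x_max, w)),
        y_max=max(0.0, min(y_max, h)),
    )


def read_detections_yolo(path: str | Path, image_w: int, image_h: int,
                         has_scores: bool = False, source: str | None = None) -> DetectionSet:
    """Parse a YOLO-format annotation/prediction file into pixel-space boxes.

    Each line is ``class cx cy w h`` (ground truth) or ``class cx cy w h conf``
    (predictions), all normalized. Boxes are denormalized, clipped to image
    bounds and returned in file order. The single object class must be 0.
    """
    path = Path(path)
    n_fields = 6 if has_scores else 5
    dets: list[Detection] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != n_fields:
            raise FormatError(
                f"{path}:{lineno}: expected {n_fields} fields, got {len(parts)}"
            )
        try:
            vals = [float(v) for v in parts]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric field") from exc
        if int(vals[0]) != 0:
            raise FormatError(f"{path}:{lineno}: only class 0 is supported, got {parts[0]}")
        cx, cy, w, h = vals[1:5]
        for v in (cx, cy, w, h):
            if not (0.0 <= v <= 1.5):
                raise FormatError(
                    f"{path}:{lineno}: normalized value {v} outside [0, 1.5]"
                )
        score = None
        if has_scores:
            score = vals[5]
            if not (0.0 <= score <= 1.0):
                raise FormatError(f"{path}:{lineno}: confidence {score} outside [0, 1]")
        box = _clip_box((cx - w / 2) * image_w, (cy - h / 2) * image_h,
                        (cx + w / 2) * image_w, (cy + h / 2) * image_h,
                        image_w, image_h)
        dets.append(Detection(box=box, score=score))
    if source is None:
        source = "external" if has_scores else "ground_truth"
    return DetectionSet(detections=dets, image_w=image_w, image_h=image_h, source=source)


def write_detections_yolo(ds: DetectionSet, path: str | Path) -> Path:
    """Write a DetectionSet as YOLO text (6 decimal places, scores iff present)."""
    path = Path(path)
    lines = []
    for det in ds:
        b = det.box
        cx = 0.5 * (b.x_min + b.x_max) / ds.image_w
        cy = 0.5 * (b.y_min + b.y_max) / ds.image_h
        w = b.width / ds.image_w
        h = b.height / ds.image_h
        fields = f"0 {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}"
        if det.score is not None:
            fields += f" {det.score:.6f}"
        lines.append(fields)
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path
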