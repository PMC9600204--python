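"""Shared geometry and image containers.

Conventions used throughout the package, stated once:

* images are ``numpy`` arrays indexed ``[row, col]`` (and ``[row, col,
  channel]`` for RGB), 8-bit unsigned;
* the electrophoresis migration axis runs along **rows**, with the point
  of application at the top of the image (row 0) and faster-migrating
  bands further down;
* patient lanes sit side by side along **columns**;
* all coordinates are 0-based and boxes are half-open,
  ``[row0, row1) x [col0, col1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import FormatError, GeometryError

#: Classifier input geometry: 150 rows (migration axis) x 30 columns.
LANE_SHAPE = (150, 30)

#: The two-class label vocabulary.
LABELS = ("normal", "thalassaemia")


@dataclass(frozen=True)
class LaneBox:
    """Half-open rectangular region assigning strip pixels to one patient."""

    row0: int
    row1: int
    col0: int
    col1: int

    def __post_init__(self) -> None:
        if not (self.row0 < self.row1 and self.col0 < self.col1):
            raise GeometryError(f"degenerate box {self}")

    @property
    def height(self) -> int:
        return self.row1 - self.row0

    @property
    def width(self) -> int:
        return self.col1 - self.col0

    def validate_within(self, shape: tuple[int, int]) -> None:
        h, w = shape[:2]
        if self.row0 < 0 or self.col0 < 0 or self.row1 > h or self.col1 > w:
            raise GeometryError(f"box {self} outside image of shape {h}x{w}")

    def column_iou(self, other: "LaneBox") -> float:
        """Intersection-over-union of the two boxes' column intervals."""
        inter = min(self.col1, other.col1) - max(self.col0, other.col0)
        if inter <= 0:
            return 0.0
        union = max(self.col1, other.col1) - min(self.col0, other.col0)
        return inter / union

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.row0, self.row1, self.col0, self.col1)


@dataclass
class StripImage:
    """RGB raster of a multi-patient strip plus provenance metadata."""

    pixels: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(
                f"strip image must be HxWx3, got shape {px.shape}"
            )
        self.pixels = px.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class LaneImage:
    """Fixed-size 30x150 RGB crop of one patient lane — the classifier input."""

    pixels: np.ndarray
    box: LaneBox | None = None
    strip_id: str | None = None
    lane_index: int | None = None
    label: str | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.shape != (*LANE_SHAPE, 3):
            raise FormatError(
                f"lane image must be {LANE_SHAPE[0]}x{LANE_SHAPE[1]}x3, "
                f"got shape {px.shape}"
            )
        self.pixels = px.astype(np.uint8, copy=False)


def as_rgb_array(image: "StripImage | LaneImage | np.ndarray") -> np.ndarray:
    """Return the underlying HxWx3 uint8 array of any image container."""
    if isinstance(image, (StripImage, LaneImage)):
        return image.pixels
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"expected HxWx3 RGB array, got shape {arr.shape}")
    return arr.astype(np.uint8, copy=False)
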