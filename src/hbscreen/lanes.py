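"""Lane detection and extraction from binarized strips.

After thresholding, each patient lane appears as one or more bright
blobs (bands) stacked along the migration axis.  Stain occasionally
bleeds between adjacent lanes, so the mask is opened with two erosion
passes at different scales (3x3 then 5x5) followed by a compensating 5x5
dilation before 8-connected component labeling.  Components are grouped
by overlapping column intervals — the bands of one patient share a
column span — and each group becomes a full-height lane box that is
cropped from the *original* RGB strip and resampled to the fixed
150x30x3 classifier input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .core import LANE_SHAPE, LaneBox, LaneImage, StripImage, as_rgb_array
from .errors import (
    DegenerateImageError,
    NoLanesError,
    ParameterError,
)
from .preprocess import preprocess_strip


def square_element(size: int) -> np.ndarray:
    """Square structuring element of odd side length."""
    if size % 2 == 0 or size < 1:
        raise ParameterError(f"structuring element side must be odd, got {size}")
    return np.ones((size, size), dtype=bool)


def erode(binary: np.ndarray, element: np.ndarray) -> np.ndarray:
    """Morphological erosion: 1 where the element fits inside foreground.

    Pixels outside the image count as background, so foreground touching
    the border is eroded from that side too.
    """
    b = _as_binary(binary)
    _check_element(element)
    return ndimage.binary_erosion(
        b, structure=element, border_value=0
    ).astype(np.uint8)


def dilate(binary: np.ndarray, element: np.ndarray) -> np.ndarray:
    """Morphological dilation: 1 where the element hits foreground."""
    b = _as_binary(binary)
    _check_element(element)
    return ndimage.binary_dilation(
        b, structure=element, border_value=0
    ).astype(np.uint8)


def separate_objects(
    binary: np.ndarray, small: int = 3, large: int = 5
) -> np.ndarray:
    """Break thin bridges between touching lanes.

    Two erosion passes at different scales (a ``small`` x ``small`` then a
    ``large`` x ``large`` square) remove narrow connections, and a single
    ``large`` x ``large`` dilation compensates most of the shrinkage.  The
    result is always contained in ``dilate(input)``.
    """
    eroded = erode(binary, square_element(small))
    eroded = erode(eroded, square_element(large))
    return dilate(eroded, square_element(large))


@dataclass
class ComponentLabeling:
    """8-connected foreground components, labeled 1..n in raster order."""

    label_map: np.ndarray
    n_components: int


def connected_components(
    binary: np.ndarray, connectivity: int = 8
) -> ComponentLabeling:
    """Label maximal connected foreground regions.

    ``connectivity`` 8 (default) joins diagonal neighbours; 4 joins only
    edge neighbours.  Labels are renumbered so component k is the k-th
    whose first pixel appears in raster (row-major) order.
    """
    b = _as_binary(binary)
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=bool)
    elif connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    else:
        raise ParameterError(f"connectivity must be 4 or 8, got {connectivity}")
    raw, n = ndimage.label(b, structure=structure)
    if n > 1:
        flat = raw.ravel()
        first = np.full(n + 1, flat.size, dtype=np.int64)
        idx = np.flatnonzero(flat)
        # reversed so earlier raster positions overwrite later ones
        first[flat[idx[::-1]]] = idx[::-1]
        order = np.argsort(first[1:], kind="stable")
        remap = np.zeros(n + 1, dtype=raw.dtype)
        remap[1 + order] = np.arange(1, n + 1)
        raw = remap[raw]
    return ComponentLabeling(label_map=raw, n_components=int(n))


@dataclass
class LaneDetection:
    """Lane boxes plus any structured warnings raised while deriving them."""

    boxes: list[LaneBox]
    warnings: list[str] = field(default_factory=list)


def lanes_from_components(
    labeling: ComponentLabeling,
    image_shape: tuple[int, int],
    min_area: int = 0,
    expected_lanes: int | None = None,
    margin: int = 2,
    merge_tol: int = 2,
    split_fallback: bool = False,
) -> LaneDetection:
    """Derive one full-height lane box per group of stacked components.

    Components smaller than ``min_area`` pixels are discarded as stain
    specks.  Surviving components whose column intervals overlap (or sit
    closer than ``merge_tol`` px) are grouped — the bands of one patient
    stack vertically and share a column span.  Each group yields a box
    spanning the full strip height and the group's column extent padded
    by ``margin`` px, clipped to the image.  If ``expected_lanes`` is set
    and the count differs, a structured warning is attached (and, only
    when ``split_fallback`` is enabled and too few lanes were found, the
    widest box is divided into equal-width parts to reach the expected
    count).
    """
    h, w = image_shape
    objects = ndimage.find_objects(labeling.label_map)
    intervals: list[tuple[int, int]] = []
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        rows, cols = sl
        area = int(np.sum(labeling.label_map[rows, cols] == lab))
        if area < min_area:
            continue
        intervals.append((cols.start, cols.stop))
    if not intervals:
        raise NoLanesError(
            "no foreground components survived the area filter"
        )

    intervals.sort()
    groups: list[list[int]] = [list(intervals[0])]
    for c0, c1 in intervals[1:]:
        if c0 < groups[-1][1] + merge_tol:
            groups[-1][1] = max(groups[-1][1], c1)
        else:
            groups.append([c0, c1])

    boxes = [
        LaneBox(0, h, max(0, c0 - margin), min(w, c1 + margin))
        for c0, c1 in groups
    ]
    warnings: list[str] = []
    if expected_lanes is not None and len(boxes) != expected_lanes:
        warnings.append(
            f"expected {expected_lanes} lanes but detected {len(boxes)}"
        )
        if split_fallback and len(boxes) < expected_lanes:
            boxes = _split_widest(boxes, expected_lanes)
            warnings.append(
                "split_fallback divided the widest box to reach "
                f"{expected_lanes} lanes"
            )
    return LaneDetection(boxes=boxes, warnings=warnings)


def _split_widest(boxes: list[LaneBox], target: int) -> list[LaneBox]:
    boxes = list(boxes)
    while len(boxes) < target:
        i = int(np.argmax([b.width for b in boxes]))
        b = boxes.pop(i)
        mid = (b.col0 + b.col1) // 2
        boxes.insert(i, LaneBox(b.row0, b.row1, mid, b.col1))
        boxes.insert(i, LaneBox(b.row0, b.row1, b.col0, mid))
    return boxes


def crop_and_resize(strip, box: LaneBox) -> LaneImage:
    """Crop ``box`` from the RGB strip and resample to 150x30 bilinearly."""
    arr = as_rgb_array(strip)
    box.validate_within(arr.shape[:2])
    crop = arr[box.row0 : box.row1, box.col0 : box.col1]
    if crop.shape[:2] == LANE_SHAPE:
        out = crop.copy()
    else:
        resized = resize(
            crop.astype(float),
            (*LANE_SHAPE, 3),
            order=1,
            mode="edge",
            anti_aliasing=None,  # applied automatically when downscaling
            preserve_range=True,
        )
        out = np.clip(np.rint(resized), 0, 255).astype(np.uint8)
    meta = strip.meta.copy() if isinstance(strip, StripImage) else {}
    return LaneImage(pixels=out, box=box, meta=meta)


@dataclass(frozen=True)
class ExtractConfig:
    """Parameters of the full lane-extraction pipeline."""

    kernel_size: int = 5
    sigma: float = 1.0
    small_scale: int = 3
    large_scale: int = 5
    min_area_frac: float = 0.0005  # 0.05 % of image pixels
    margin: int = 2
    merge_tol: int = 2
    expected_lanes: int | None = 8
    split_fallback: bool = False


def detect_lanes(
    strip, config: ExtractConfig = ExtractConfig()
) -> LaneDetection:
    """Run preprocessing, opening and component grouping; return boxes."""
    arr = as_rgb_array(strip)
    try:
        binary = preprocess_strip(arr, config.kernel_size, config.sigma)
    except DegenerateImageError as exc:
        raise NoLanesError(f"no foreground to segment: {exc}") from exc
    separated = separate_objects(
        binary, config.small_scale, config.large_scale
    )
    labeling = connected_components(separated, connectivity=8)
    if labeling.n_components == 0:
        raise NoLanesError("binarized strip contains no foreground")
    min_area = int(round(config.min_area_frac * arr.shape[0] * arr.shape[1]))
    return lanes_from_components(
        labeling,
        arr.shape[:2],
        min_area=min_area,
        expected_lanes=config.expected_lanes,
        margin=config.margin,
        merge_tol=config.merge_tol,
        split_fallback=config.split_fallback,
    )


def extract_lanes(
    strip, config: ExtractConfig = ExtractConfig()
) -> tuple[list[LaneImage], list[str]]:
    """Full pipeline: one 150x30 RGB lane image per detected lane,
    ordered left to right, plus the warning channel."""
    detection = detect_lanes(strip, config)
    lanes = []
    for k, box in enumerate(detection.boxes):
        lane = crop_and_resize(strip, box)
        lane.lane_index = k
        if isinstance(strip, StripImage):
            lane.strip_id = strip.meta.get("path")
        lanes.append(lane)
    return lanes, detection.warnings


def _as_binary(binary: np.ndarray) -> np.ndarray:
    arr = np.asarray(binary)
    if arr.ndim != 2:
        raise ParameterError(f"expected 2-D binary array, got {arr.shape}")
    if arr.dtype == bool:
        return arr
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, [0, 1])):
        raise ParameterError("binary image must contain only {0, 1}")
    return arr.astype(bool)


def _check_element(element: np.ndarray) -> None:
    el = np.asarray(element)
    if el.ndim != 2 or el.shape[0] % 2 == 0 or el.shape[1] % 2 == 0:
        raise ParameterError("structuring element must be 2-D with odd sides")
    if not el[el.shape[0] // 2, el.shape[1] // 2]:
        raise ParameterError("structuring element anchor must be set")
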