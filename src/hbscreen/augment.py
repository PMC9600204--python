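"""Training-set augmentation for lane images.

Each training image is expanded into itself plus 14 geometric variants,
cycling through three strategies — clockwise rotation of 3-5 degrees,
center magnification of 2.5-10 %, and horizontal+vertical translation of
5-10 % of the image size — with the parameter of each variant drawn
uniformly from its range by a seeded generator.  Outputs keep the fixed
150x30x3 geometry (border replication fills uncovered pixels), carry
their source image and transform parameters in ``meta``, and are
bit-reproducible under a fixed seed.  Only training images are ever
augmented; validation and test sets stay untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import LaneImage
from .errors import InvalidSpecError

STRATEGIES = ("rotation", "scale", "translate")


@dataclass(frozen=True)
class AugmentSpec:
    """Ranges of the three augmentation strategies and the variant count."""

    rotation_deg_range: tuple[float, float] = (3.0, 5.0)  # clockwise
    scale_frac_range: tuple[float, float] = (0.025, 0.10)
    translate_frac_range: tuple[float, float] = (0.05, 0.10)
    n_variants: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise InvalidSpecError("n_variants must be >= 1")
        for lo, hi in (
            self.rotation_deg_range,
            self.scale_frac_range,
            self.translate_frac_range,
        ):
            if not (0 <= lo <= hi):
                raise InvalidSpecError("augmentation ranges must be 0 <= lo <= hi")


def _rotate_cw(arr: np.ndarray, degrees: float) -> np.ndarray:
    # In image coordinates (rows down), a visually clockwise rotation is
    # a negative-angle rotation for scipy's row/col axes order.
    return ndimage.rotate(
        arr,
        angle=-degrees,
        axes=(0, 1),
        reshape=False,
        order=1,
        mode="nearest",
    )


def _magnify(arr: np.ndarray, scale: float) -> np.ndarray:
    # Center-anchored magnification: inverse-map output coords through a
    # 1/scale zoom about the image center, then the implicit center crop
    # is free because the output grid equals the input grid.
    h, w = arr.shape[:2]
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    matrix = np.array([1.0 / scale, 1.0 / scale])
    offset = center - center / scale
    out = np.empty_like(arr)
    for ch in range(arr.shape[2]):
        out[..., ch] = ndimage.affine_transform(
            arr[..., ch],
            matrix,
            offset=offset,
            order=1,
            mode="nearest",
        )
    return out


def _translate(arr: np.ndarray, dr: float, dc: float) -> np.ndarray:
    return ndimage.shift(
        arr, shift=(dr, dc, 0.0), order=1, mode="nearest"
    )


def _apply_variant(
    pixels: np.ndarray, strategy: str, rng: np.random.Generator,
    spec: AugmentSpec,
) -> tuple[np.ndarray, dict]:
    arr = pixels.astype(float)
    if strategy == "rotation":
        angle = rng.uniform(*spec.rotation_deg_range)
        out = _rotate_cw(arr, angle)
        params = {"degrees_cw": angle}
    elif strategy == "scale":
        frac = rng.uniform(*spec.scale_frac_range)
        out = _magnify(arr, 1.0 + frac)
        params = {"magnification_frac": frac}
    elif strategy == "translate":
        h, w = arr.shape[:2]
        fr = rng.uniform(*spec.translate_frac_range)
        fc = rng.uniform(*spec.translate_frac_range)
        dr = fr * h * rng.choice([-1.0, 1.0])
        dc = fc * w * rng.choice([-1.0, 1.0])
        out = _translate(arr, dr, dc)
        params = {"shift_rows_px": dr, "shift_cols_px": dc}
    else:  # pragma: no cover - guarded by STRATEGIES
        raise InvalidSpecError(f"unknown strategy {strategy!r}")
    clipped = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return clipped, params


def augment_image(
    lane: LaneImage,
    spec: AugmentSpec = AugmentSpec(),
    rng: np.random.Generator | None = None,
) -> list[LaneImage]:
    """Return the original lane followed by ``n_variants`` variants.

    Variant k applies one strategy, cycling rotation -> scale ->
    translate; its parameters are logged in the variant's ``meta`` under
    ``"augment"``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    out = [lane]
    for k in range(spec.n_variants):
        strategy = STRATEGIES[k % len(STRATEGIES)]
        pixels, params = _apply_variant(lane.pixels, strategy, rng, spec)
        meta = dict(lane.meta)
        meta["augment"] = {"strategy": strategy, **params}
        meta["source_image"] = _source_name(lane)
        out.append(
            LaneImage(
                pixels=pixels,
                box=lane.box,
                strip_id=lane.strip_id,
                lane_index=lane.lane_index,
                label=lane.label,
                meta=meta,
            )
        )
    return out


def augment_set(
    lanes: list[LaneImage], spec: AugmentSpec = AugmentSpec()
) -> list[LaneImage]:
    """Augment every lane; output count is exactly 15x the input count
    (original first in each block), labels and provenance preserved."""
    rng = np.random.default_rng(spec.seed)
    out: list[LaneImage] = []
    for lane in lanes:
        out.extend(augment_image(lane, spec, rng=rng))
    return out


def _source_name(lane: LaneImage) -> str:
    sid = lane.strip_id if lane.strip_id is not None else "<memory>"
    idx = lane.lane_index if lane.lane_index is not None else "?"
    return f"{sid}:lane{idx}"
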