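"""Gradient-free class-activation saliency (Score-CAM).

For a chosen convolutional activation of a trained network, each channel
is min-max normalized, bilinearly upsampled to the input size, and used
to mask the input (elementwise product, zero baseline elsewhere); the
masked input's forward-pass softmax score for the target class becomes
that channel's weight.  The saliency map is the rectified weighted sum
of the normalized upsampled channels, min-max normalized to [0, 1].
High values mark image regions that drive the class decision — on lane
images these should sit on the haemoglobin bands.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from .classify import TrainedModel
from .core import LaneImage, as_rgb_array
from .errors import GeometryError, ParameterError
from .nn import lanes_to_batch, softmax


def _normalize_map(arr: np.ndarray) -> np.ndarray:
    lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def _upsample(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if arr.shape == shape:
        return arr.copy()
    return resize(arr, shape, order=1, mode="edge", preserve_range=True,
                  anti_aliasing=False)


def scorecam_map(
    trained: TrainedModel,
    lane: LaneImage,
    target: str,
    layer: str | None = None,
) -> np.ndarray:
    """Saliency map in [0, 1] with the lane image's spatial dims.

    ``layer`` must name a convolutional activation of the model; the
    default is the last one.  An input for which every channel weight
    or activation vanishes yields the all-zero map.
    """
    model = trained.model
    conv_layers = model.conv_layer_names()
    if layer is None:
        if not conv_layers:
            raise ParameterError("model has no convolutional activations")
        layer = conv_layers[-1]
    elif layer not in conv_layers:
        raise ParameterError(
            f"layer {layer!r} is not a convolutional activation; "
            f"choose from {conv_layers}"
        )
    if target not in trained.classes:
        raise ParameterError(f"unknown target class {target!r}")
    target_idx = trained.classes.index(target)

    x = lanes_to_batch([as_rgb_array(lane)])  # (1, 3, H, W)
    h, w = x.shape[2], x.shape[3]
    acts = model.activations(x, layer)[0]  # (C, h', w')

    upsampled = np.stack(
        [_upsample(_normalize_map(a), (h, w)) for a in acts]
    )
    masked = x * upsampled[:, None, :, :]  # (C, 3, H, W)
    logits = np.concatenate(
        [model.forward(masked[i:i + 16]) for i in range(0, len(masked), 16)]
    )
    weights = softmax(logits)[:, target_idx]

    cam = np.einsum("c,chw->hw", weights, upsampled)
    cam = np.maximum(cam, 0.0)
    return _normalize_map(cam)


def overlay(
    saliency: np.ndarray,
    lane: LaneImage,
    alpha: float = 0.4,
    colormap: str = "jet",
) -> np.ndarray:
    """Alpha-blend a blue-to-red heat map over the lane image.

    Returns an HxWx3 uint8 image; ``alpha`` 0 returns the lane
    unchanged, low saliency renders blue and high saliency red.
    """
    arr = as_rgb_array(lane).astype(float)
    sal = np.asarray(saliency, dtype=float)
    if sal.shape != arr.shape[:2]:
        raise GeometryError(
            f"saliency {sal.shape} does not match image {arr.shape[:2]}"
        )
    if not (0.0 <= alpha <= 1.0):
        raise ParameterError("alpha must be in [0, 1]")
    if alpha == 0.0:
        return arr.astype(np.uint8)
    import matplotlib

    cmap = matplotlib.colormaps[colormap]
    heat = cmap(np.clip(sal, 0.0, 1.0))[..., :3] * 255.0
    blended = (1.0 - alpha) * arr + alpha * heat
    return np.clip(np.rint(blended), 0, 255).astype(np.uint8)
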