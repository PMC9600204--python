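"""Minimal CPU neural-network stack for lane-image classification.

Implements exactly the pieces the screening classifier needs — same-pad
3x3 convolution (im2col), ReLU, non-overlapping max pooling, a linear
head, softmax cross-entropy and the Adam optimizer — on float32 numpy
arrays in NCHW layout.  The stack exposes per-layer activations so the
Score-CAM saliency module can read convolutional feature maps, and every
weight initialization is driven by an explicit seed.

``TinyCNN`` is the compact reference architecture: two conv blocks
(conv-ReLU-maxpool), flatten, linear head — a few thousand parameters,
trainable in seconds on a single core.
"""

from __future__ import annotations

import copy

import numpy as np

from .errors import FormatError, ParameterError


def _sliding_cols(xp: np.ndarray, k: int) -> np.ndarray:
    """im2col: padded (N,C,Hp,Wp) -> (N*H*W, C*k*k) patch matrix."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    n, c, h, w = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
    return np.ascontiguousarray(cols)


class Conv2D:
    """3x3 (or any odd k) same-padding convolution, stride 1."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, *,
                 rng: np.random.Generator):
        if k % 2 == 0:
            raise ParameterError("kernel size must be odd")
        self.k = k
        self.in_ch = in_ch
        self.out_ch = out_ch
        fan_in = in_ch * k * k
        self.W = (rng.standard_normal((fan_in, out_ch))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = _sliding_cols(xp, self.k)
        self._cols, self._shape = cols, x.shape
        y = cols @ self.W + self.b
        return y.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        k, p = self.k, self.k // 2
        dyc = dy.transpose(0, 2, 3, 1).reshape(-1, self.out_ch)
        self.dW = self._cols.T @ dyc
        self.db = dyc.sum(axis=0)
        dcols = (dyc @ self.W.T).reshape(n, h, w, self.in_ch, k, k)
        dxp = np.zeros((n, self.in_ch, h + 2 * p, w + 2 * p),
                       dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di:di + h, dj:dj + w] += (
                    dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
                )
        return dxp[:, :, p:p + h, p:p + w]

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)

    def params(self):
        return []


class MaxPool:
    """Non-overlapping p x p max pooling; spatial dims must divide p."""

    def __init__(self, p: int):
        self.p = p

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.p
        if h % p or w % p:
            raise FormatError(f"pool {p} does not divide {h}x{w}")
        xr = (x.reshape(n, c, h // p, p, w // p, p)
               .transpose(0, 1, 2, 4, 3, 5)
               .reshape(n, c, h // p, w // p, p * p))
        self._argmax = xr.argmax(axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(
            xr, self._argmax[..., None], axis=-1
        )[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._inshape
        p = self.p
        dxr = np.zeros((n, c, h // p, w // p, p * p), dtype=np.float32)
        np.put_along_axis(dxr, self._argmax[..., None], dy[..., None],
                          axis=-1)
        return (dxr.reshape(n, c, h // p, w // p, p, p)
                   .transpose(0, 1, 2, 4, 3, 5)
                   .reshape(n, c, h, w))

    def params(self):
        return []


class Flatten:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)

    def params(self):
        return []


class Linear:
    def __init__(self, n_in: int, n_out: int, *, rng: np.random.Generator):
        self.W = (rng.standard_normal((n_in, n_out))
                  * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    loss = -np.mean(np.log(probs[np.arange(n), targets] + 1e-12))
    grad = probs.copy()
    grad[np.arange(n), targets] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


class Adam:
    """Adaptive-moment optimizer (beta1=0.9, beta2=0.999)."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}
        self._t = 0

    def step(self, layers) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for layer in layers:
            for name, p, g in layer.params():
                key = id(p)
                m = self._m.setdefault(key, np.zeros_like(p))
                v = self._v.setdefault(key, np.zeros_like(p))
                m += (1 - b1) * (g - m)
                v += (1 - b2) * (g * g - v)
                mh = m / (1 - b1**self._t)
                vh = v / (1 - b2**self._t)
                p -= self.lr * mh / (np.sqrt(vh) + self.eps)


class SequentialModel:
    """Named layer stack with activation capture for saliency methods."""

    def __init__(self, layers: list[tuple[str, object]], n_classes: int = 2):
        self.layer_names = [name for name, _ in layers]
        self.layers = [layer for _, layer in layers]
        self.n_classes = n_classes

    def forward(self, x: np.ndarray,
                capture: str | None = None) -> np.ndarray:
        out = x
        captured = None
        for name, layer in zip(self.layer_names, self.layers):
            out = layer.forward(out)
            if name == capture:
                captured = out
        if capture is not None:
            if captured is None:
                raise ParameterError(f"no layer named {capture!r}")
            self.captured = captured
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def predict_proba(self, x: np.ndarray,
                      batch_size: int = 64) -> np.ndarray:
        chunks = [
            softmax(self.forward(x[i:i + batch_size]))
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(chunks, axis=0)

    def activations(self, x: np.ndarray, layer: str) -> np.ndarray:
        self.forward(x, capture=layer)
        return self.captured

    def conv_layer_names(self) -> list[str]:
        """Names of ReLU activations that follow a convolution."""
        names = []
        for i, layer in enumerate(self.layers):
            if isinstance(layer, ReLU) and i > 0 and isinstance(
                self.layers[i - 1], Conv2D
            ):
                names.append(self.layer_names[i])
        return names

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            for name, p, *_ in _param_views(layer):
                out.append(p.copy())
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            for name, p, *_ in _param_views(layer):
                np.copyto(p, weights[i])
                i += 1

    def clone_weights(self) -> list[np.ndarray]:
        return copy.deepcopy(self.get_weights())


def _param_views(layer):
    if isinstance(layer, (Conv2D, Linear)):
        return [("W", layer.W), ("b", layer.b)]
    return []


def build_tinycnn(seed: int = 0, n_classes: int = 2) -> SequentialModel:
    """Two conv blocks + pooling + linear head for 150x30x3 inputs.

    conv(3->8) ReLU pool2 -> 75x15; conv(8->16) ReLU pool3 -> 25x5;
    flatten (2000) -> linear -> class logits.  ~5.4k parameters.
    """
    rng = np.random.default_rng(seed)
    return SequentialModel(
        [
            ("conv1", Conv2D(3, 8, 3, rng=rng)),
            ("relu1", ReLU()),
            ("pool1", MaxPool(2)),
            ("conv2", Conv2D(8, 16, 3, rng=rng)),
            ("relu2", ReLU()),
            ("pool2", MaxPool(3)),
            ("flatten", Flatten()),
            ("fc", Linear(16 * 25 * 5, n_classes, rng=rng)),
        ],
        n_classes=n_classes,
    )


def lanes_to_batch(pixels_list) -> np.ndarray:
    """Stack HxWx3 uint8 lane images into a normalized NCHW float batch.

    Each image is standardized to zero mean and unit variance over all
    its pixels and channels, which removes per-lane illumination and
    background-tint offsets and leaves the band pattern as the signal.
    """
    arr = np.stack([np.asarray(p, dtype=np.float32) for p in pixels_list])
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise FormatError(f"expected N x H x W x 3 stack, got {arr.shape}")
    arr = arr.transpose(0, 3, 1, 2) / 255.0
    mu = arr.mean(axis=(1, 2, 3), keepdims=True)
    sd = arr.std(axis=(1, 2, 3), keepdims=True)
    return np.ascontiguousarray((arr - mu) / (sd + 1e-6))
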