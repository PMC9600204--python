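"""Independent brute-force oracles used to cross-check the pipeline.

Each function here re-derives a quantity from first principles (explicit
enumeration, flood fill, all-pairs counting) without touching the
implementation under test.
"""

import numpy as np


def otsu_brute_force(gray: np.ndarray) -> int:
    """Exhaustive scan of all 255 candidate thresholds.

    For each t, class 0 is {v <= t} and class 1 is {v > t}; returns the
    smallest t maximizing the between-class variance
    w0*w1*(mu0 - mu1)^2.
    """
    values = gray.ravel().astype(float)
    n = values.size
    best_t, best_var = 0, -1.0
    for t in range(255):
        c0 = values[values <= t]
        c1 = values[values > t]
        if c0.size == 0 or c1.size == 0:
            var = -np.inf
        else:
            w0, w1 = c0.size / n, c1.size / n
            var = w0 * w1 * (c0.mean() - c1.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def flood_fill_components(mask: np.ndarray, connectivity: int = 8):
    """Label components by explicit stack-based flood fill.

    Labels are assigned 1..n in raster order of each component's first
    pixel.  Returns (label_map, n_components).
    """
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    current = 0
    for r in range(h):
        for c in range(w):
            if mask[r, c] and labels[r, c] == 0:
                current += 1
                stack = [(r, c)]
                labels[r, c] = current
                while stack:
                    rr, cc = stack.pop()
                    for dr, dc in nbrs:
                        r2, c2 = rr + dr, cc + dc
                        if (0 <= r2 < h and 0 <= c2 < w
                                and mask[r2, c2] and labels[r2, c2] == 0):
                            labels[r2, c2] = current
                            stack.append((r2, c2))
    return labels, current


def auc_all_pairs(y_true, scores) -> float:
    """Mann-Whitney AUC: concordant-pair fraction with half-credit ties."""
    pos = [s for y, s in zip(y_true, scores) if y]
    neg = [s for y, s in zip(y_true, scores) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def scorecam_reference(model, pixels, target_idx, layer):
    """Step-by-step re-derivation of the masked-forward saliency recipe.

    Works channel by channel with its own normalization, upsampling and
    weighting; only the model's forward pass is shared with the
    implementation under test.
    """
    from skimage.transform import resize

    arr = np.asarray(pixels, dtype=np.float64) / 255.0
    x = arr.transpose(2, 0, 1)[None]
    x = (x - x.mean()) / (x.std() + 1e-6)
    x = x.astype(np.float32)
    acts = model.activations(x, layer)[0]
    h, w = arr.shape[:2]
    cam = np.zeros((h, w))
    for ch in range(acts.shape[0]):
        a = acts[ch].astype(np.float64)
        lo, hi = a.min(), a.max()
        norm = (a - lo) / (hi - lo) if hi > lo else np.zeros_like(a)
        if norm.shape == (h, w):
            up = norm
        else:
            up = resize(norm, (h, w), order=1, mode="edge",
                        preserve_range=True, anti_aliasing=False)
        masked = (x[0] * up[None]).astype(np.float32)[None]
        logits = model.forward(masked)[0]
        e = np.exp(logits - logits.max())
        weight = (e / e.sum())[target_idx]
        cam += weight * up
    cam = np.maximum(cam, 0.0)
    lo, hi = cam.min(), cam.max()
    return (cam - lo) / (hi - lo) if hi > lo else np.zeros_like(cam)
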