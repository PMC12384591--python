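"""Gradient-weighted class activation maps on the final convolutional layer.

For a window and target class c the map is built in four steps: (i) a forward
pass records the target-layer activations A^k and the class logits; (ii) the
gradient of the class logit y_c (pre-softmax) w.r.t. A^k is computed exactly by
backpropagation; (iii) each feature map's gradient is globally average-pooled
over its H x W extent into a weight alpha_k = (1/Z) sum_ij dy_c/dA^k_ij with
Z = H*W; (iv) the alpha-weighted sum of feature maps is ReLU-clipped and
bilinearly upsampled to the input grid (time x channel, 128 x 32 for the
canonical network), so each column of the result scores one EEG electrode.

Arrays at the feature level are (H, W, K); any model exposing the
``target_forward(x) -> (acts, logits)`` / ``target_backward(class_idx) -> grads``
protocol (activations as (N, K, H, W)) can be explained.
"""

from __future__ import annotations

import numpy as np


def _n_classes(model) -> int:
    return model.n_classes if hasattr(model, "n_classes") else model.spec.n_classes


def _window_to_image(window: np.ndarray, dtype) -> np.ndarray:
    window = np.asarray(window)
    if window.ndim != 2:
        raise ValueError(f"window must be 2-D (channels x time), got ndim={window.ndim}")
    return np.ascontiguousarray(window.T)[None, None, :, :].astype(dtype)


def target_layer_forward(model, window: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Target-layer activations (H, W, K) and the pre-softmax logit vector."""
    acts, logits = model.target_forward(_window_to_image(window, model.dtype))
    return acts[0].transpose(1, 2, 0), logits[0]


def class_gradients(model, window: np.ndarray, c: int) -> np.ndarray:
    """Exact gradient of logit y_c w.r.t. the target activations, shape (H, W, K)."""
    if not 0 <= c < _n_classes(model):
        raise ValueError(f"class index {c} outside [0, {_n_classes(model)})")
    model.target_forward(_window_to_image(window, model.dtype))
    grads = model.target_backward(np.array([c]))
    return grads[0].transpose(1, 2, 0)


def pool_gradients(grads: np.ndarray) -> np.ndarray:
    """Global-average-pool (H, W, K) gradients into per-feature-map weights alpha (K,)."""
    return np.asarray(grads).mean(axis=(0, 1))


def weighted_map(weights: np.ndarray, acts: np.ndarray) -> np.ndarray:
    """ReLU of the alpha-weighted sum of feature maps; shape (H, W), entries >= 0."""
    weights = np.asarray(weights)
    acts = np.asarray(acts)
    if weights.shape[0] != acts.shape[2]:
        raise ValueError(f"got {weights.shape[0]} weights for {acts.shape[2]} feature maps")
    return np.maximum(acts @ weights, 0.0)


def _axis_interp(size_in: int, size_out: int):
    # half-pixel centers, no corner alignment
    pos = (np.arange(size_out) + 0.5) * size_in / size_out - 0.5
    pos = np.clip(pos, 0.0, size_in - 1.0)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, size_in - 1)
    return lo, hi, pos - lo


def upsample_to_input(m: np.ndarray, out_shape: tuple[int, int] = (128, 32)) -> np.ndarray:
    """Bilinear upsampling to the input grid; preserves non-negativity and constants."""
    m = np.asarray(m, dtype=np.float64)
    lo_r, hi_r, fr_r = _axis_interp(m.shape[-2], out_shape[0])
    lo_c, hi_c, fr_c = _axis_interp(m.shape[-1], out_shape[1])
    rows = m[..., lo_r, :] * (1.0 - fr_r)[:, None] + m[..., hi_r, :] * fr_r[:, None]
    return rows[..., :, lo_c] * (1.0 - fr_c) + rows[..., :, hi_c] * fr_c


def gradcam(model, window: np.ndarray, c: int | None = None) -> np.ndarray:
    """Class activation map on the input grid (time x channel), entries >= 0.

    ``c`` defaults to the model's predicted class for the window.
    """
    acts, logits = target_layer_forward(model, window)
    if c is None:
        c = int(np.argmax(logits))
    grads = class_gradients(model, window, c)
    raw = weighted_map(pool_gradients(grads), acts)
    out_shape = (window.shape[1], window.shape[0])
    return upsample_to_input(raw, out_shape)


def gradcam_batch(
    model,
    X: np.ndarray,
    classes: np.ndarray | str | int = "predicted",
    batch_size: int = 240,
) -> np.ndarray:
    """Maps for many windows at once; returns (n, time, channels).

    ``classes`` is an explicit per-window class array (e.g. the true labels), a
    single class index, or ``"predicted"``.
    """
    X = np.asarray(X)
    n, n_ch, n_t = X.shape
    out = np.empty((n, n_t, n_ch))
    for start in range(0, n, batch_size):
        xb = X[start : start + batch_size]
        imgs = np.ascontiguousarray(xb.transpose(0, 2, 1))[:, None, :, :].astype(model.dtype)
        acts, logits = model.target_forward(imgs)
        if isinstance(classes, str):
            if classes != "predicted":
                raise ValueError("classes must be an array, an int, or 'predicted'")
            cls = logits.argmax(axis=1)
        elif np.isscalar(classes):
            cls = np.full(xb.shape[0], int(classes))
        else:
            cls = np.asarray(classes)[start : start + batch_size]
        grads = model.target_backward(cls)
        alpha = grads.mean(axis=(2, 3))  # (n, K)
        raw = np.maximum(np.einsum("nkhw,nk->nhw", acts, alpha), 0.0)
        out[start : start + xb.shape[0]] = upsample_to_input(raw, (n_t, n_ch))
    return out
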