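"""Minimal numpy/numba layers with explicit forward/backward passes.

Implemented from scratch because the pipeline needs exact intermediate gradients
(logit w.r.t. target-layer activations) as well as training. Tensors are
channel-first, (N, C, H, W): convolutions are stride-1 with zero padding and run
through compiled row-vectorised kernels (with a pure-numpy fallback), pooling
acts on the temporal (H) axis only, and dropout on conv blocks is structured
(whole feature maps drop together).
"""

from __future__ import annotations

import numpy as np

try:  # compiled conv kernels; the numpy path below is a drop-in fallback
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap


@njit(fastmath=True, cache=True)
def _conv_fwd_kernel(xp, weights, out):  # pragma: no cover - compiled
    # xp (N, Cin, Hp, Wp), weights (Cout, Cin, kh, kw), out (N, Cout, H, W)
    n_batch, cout, h, w = out.shape
    _, cin, kh, kw = weights.shape
    for n in range(n_batch):
        for o in range(cout):
            for c in range(cin):
                for i in range(kh):
                    for j in range(kw):
                        wv = weights[o, c, i, j]
                        for y in range(h):
                            row_in = xp[n, c, y + i]
                            row_out = out[n, o, y]
                            for x in range(w):
                                row_out[x] += wv * row_in[x + j]


@njit(fastmath=True, cache=True)
def _conv_dw_kernel(xp, dout, dweights):  # pragma: no cover - compiled
    n_batch, cout, h, w = dout.shape
    _, cin, kh, kw = dweights.shape
    for n in range(n_batch):
        for o in range(cout):
            for c in range(cin):
                for i in range(kh):
                    for j in range(kw):
                        acc = 0.0
                        for y in range(h):
                            row_d = dout[n, o, y]
                            row_x = xp[n, c, y + i]
                            for x in range(w):
                                acc += row_d[x] * row_x[x + j]
                        dweights[o, c, i, j] += acc


class Conv2D:
    """Stride-1 zero-padded 2-D convolution preserving spatial size.

    Weights are (out_ch, in_ch, kh, kw).
    """

    def __init__(self, in_ch: int, out_ch: int, kh: int, kw: int, rng, dtype=np.float32):
        fan_in = in_ch * kh * kw
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kh, kw)).astype(dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.kh, self.kw = kh, kw
        self._xp = None

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    @property
    def weight_names(self):
        return ("W",)

    @staticmethod
    def _correlate(xp: np.ndarray, weights: np.ndarray, h: int, w: int) -> np.ndarray:
        """Valid cross-correlation of a padded input with the kernel bank."""
        cout, cin, kh, kw = weights.shape
        n = xp.shape[0]
        out = np.zeros((n, cout, h, w), dtype=xp.dtype)
        if _HAVE_NUMBA:
            _conv_fwd_kernel(xp, np.ascontiguousarray(weights), out)
            return out
        acc = np.zeros((n, h, w, cout), dtype=xp.dtype)
        for i in range(kh):
            for j in range(kw):
                slab = xp[:, :, i : i + h, j : j + w]
                acc += np.einsum("nchw,oc->nhwo", slab, weights[:, :, i, j])
        out[...] = acc.transpose(0, 3, 1, 2)
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, cin, h, w = x.shape
        ph, pw = self.kh // 2, self.kw // 2
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x
        self._xp = np.ascontiguousarray(xp)
        self._hw = (h, w)
        return self._correlate(self._xp, self.W, h, w) + self.b[:, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, (h, w) = self._xp, self._hw
        dout = np.ascontiguousarray(dout)
        dW = np.zeros_like(self.W)
        if _HAVE_NUMBA:
            _conv_dw_kernel(xp, dout, dW)
        else:
            for i in range(self.kh):
                for j in range(self.kw):
                    slab = xp[:, :, i : i + h, j : j + w]
                    dW[:, :, i, j] = np.tensordot(dout, slab, axes=([0, 2, 3], [0, 2, 3]))
        self.grads = {"W": dW, "b": dout.sum(axis=(0, 2, 3))}
        # input gradient = correlation of dout with the spatially flipped,
        # in/out-transposed kernel
        ph, pw = self.kh // 2, self.kw // 2
        dp = np.pad(dout, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else dout
        wrot = np.ascontiguousarray(self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
        return self._correlate(np.ascontiguousarray(dp), wrot, h, w)


class Dense:
    def __init__(self, in_dim: int, out_dim: int, rng, dtype=np.float32):
        self.W = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(out_dim, in_dim)).astype(dtype)
        self.b = np.zeros(out_dim, dtype=dtype)
        self._cache = None

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    @property
    def weight_names(self):
        return ("W",)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return x @ self.W.T + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self.grads = {"W": dout.T @ x, "b": dout.sum(axis=0)}
        return dout @ self.W


class BatchNorm:
    """Batch normalisation over all axes except the feature axis (axis 1).

    ``axes=(0, 2, 3)`` normalises per feature map for (N, C, H, W) tensors,
    ``axes=(0,)`` per unit for (N, U) tensors. Inference uses exponential
    running statistics, under which the layer is an affine map.
    """

    def __init__(self, n_features: int, axes=(0, 2, 3), momentum: float = 0.9, eps: float = 1e-5, dtype=np.float32):
        self.gamma = np.ones(n_features, dtype=dtype)
        self.beta = np.zeros(n_features, dtype=dtype)
        self.running_mean = np.zeros(n_features, dtype=dtype)
        self.running_var = np.ones(n_features, dtype=dtype)
        self.axes = axes
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    @property
    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    @property
    def weight_names(self):  # BN scales are not L2-penalised
        return ()

    def _bc(self, v: np.ndarray, ndim: int) -> np.ndarray:
        shape = [1] * ndim
        shape[1] = -1
        return v.reshape(shape)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        nd = x.ndim
        if train:
            mean = x.mean(axis=self.axes)
            var = x.var(axis=self.axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            xhat = (x - self._bc(mean, nd)) / np.sqrt(self._bc(var, nd) + self.eps)
            self._cache = ("train", xhat, var)
        else:
            xhat = (x - self._bc(self.running_mean, nd)) / np.sqrt(self._bc(self.running_var, nd) + self.eps)
            self._cache = ("eval", xhat, self.running_var)
        return self._bc(self.gamma, nd) * xhat + self._bc(self.beta, nd)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mode, xhat, var = self._cache
        nd = dout.ndim
        self.grads = {
            "gamma": (dout * xhat).sum(axis=self.axes),
            "beta": dout.sum(axis=self.axes),
        }
        inv_std = 1.0 / np.sqrt(self._bc(var, nd) + self.eps)
        if mode == "eval":  # running stats are constants
            return dout * self._bc(self.gamma, nd) * inv_std
        m = np.prod([dout.shape[a] for a in self.axes])
        dxhat = dout * self._bc(self.gamma, nd)
        return (
            inv_std
            / m
            * (
                m * dxhat
                - self._bc(dxhat.sum(axis=self.axes), nd)
                - xhat * self._bc((dxhat * xhat).sum(axis=self.axes), nd)
            )
        )


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout:
    """Inverted dropout with retention probability ``keep``.

    ``structured=True`` draws one Bernoulli per feature map (noise shape
    (N, C, 1, 1)) so entire channels deactivate together.
    """

    def __init__(self, keep: float, structured: bool = False):
        if not 0.0 < keep <= 1.0:
            raise ValueError("keep probability must be in (0, 1]")
        self.keep = keep
        self.structured = structured
        self._mask = None

    def forward(self, x: np.ndarray, train: bool, rng=None) -> np.ndarray:
        if not train or self.keep >= 1.0:
            self._mask = None
            return x
        shape = (x.shape[0], x.shape[1], 1, 1) if self.structured else x.shape
        self._mask = (rng.random(shape) < self.keep).astype(x.dtype) / self.keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class MaxPoolTime:
    """Max pooling with size and stride (2, 1): halves the temporal (H) axis only."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2:
            raise ValueError(f"temporal dimension {h} must be even for (2,1) pooling")
        xr = x.reshape(n, c, h // 2, 2, w)
        self._argmax = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, 2, w), dtype=dout.dtype)
        np.put_along_axis(dxr, self._argmax[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        return dxr.reshape(n, c, h, w)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), (dlogits / n).astype(logits.dtype)


class Adam:
    """Adam over a ``{name: array}`` parameter dict; updates in place."""

    def __init__(self, params: dict, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, grads: dict, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
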