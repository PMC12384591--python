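"""The 2-D CNN for windowed EEG classification.

Topology: six 5x5 stride-1 zero-padded convolutions with (2,1) max pooling after
conv3 and conv6 (temporal axis 128 -> 64 -> 32), residual links conv1->conv3 and
conv4->conv6 (1x1 projection when filter counts differ), then flatten -> fc1 ->
N-way output. Regularisation: structured dropout after conv1/conv3/conv4/conv6
and fc1, batch normalisation after conv2/conv4/conv5 and fc1, L2 weight decay in
the loss, and a learning rate halved every ``lr_half_life`` epochs. Training uses
Adam on softmax cross-entropy.

Input windows are channels x time (32 x 128); internally tensors are
channel-first images (N, feature maps, H=time, W=EEG channel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import (
    Adam,
    BatchNorm,
    Conv2D,
    Dense,
    Dropout,
    MaxPoolTime,
    ReLU,
    softmax,
    softmax_cross_entropy,
)


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture plus training hyperparameters.

    The canonical configuration (:meth:`canonical`) reproduces the published
    layer table exactly; :meth:`scaled` keeps the topology but shrinks every
    filter bank by an integer factor for CPU-budget experiments.
    """

    n_classes: int = 4
    input_shape: tuple[int, int] = (128, 32)  # (time, channels)
    conv_filters: tuple[int, ...] = (32, 32, 64, 64, 64, 128)
    kernel: tuple[int, int] = (5, 5)
    pool: tuple[int, int] = (2, 1)
    fc1_units: int = 512
    residual_links: tuple[tuple[int, int], ...] = ((1, 3), (4, 6))
    dropout_keep: float = 0.5
    dropout_at: tuple = (1, 3, 4, 6, "fc1")
    batchnorm_at: tuple = (2, 4, 5, "fc1")
    l2_coeff: float = 1e-4
    lr0: float = 1e-3
    lr_half_life: int = 50
    batch_size: int = 240
    epochs: int = 200

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 6:
            raise ValueError("conv_filters must list exactly six filter counts")
        if self.n_classes not in (2, 4):
            raise ValueError("n_classes must be 2 or 4")
        if not 0.0 < self.dropout_keep <= 1.0:
            raise ValueError("dropout_keep must be in (0, 1]")
        if self.pool != (2, 1):
            raise ValueError("pooling is fixed at size/stride (2, 1) on the temporal axis")
        for link in self.residual_links:
            if tuple(link) not in ((1, 3), (4, 6)):
                raise ValueError("residual links are fixed at conv1->conv3 and conv4->conv6")

    @classmethod
    def canonical(cls, n_classes: int = 4, **overrides) -> "NetworkSpec":
        return cls(n_classes=n_classes, **overrides)

    @classmethod
    def scaled(cls, n_classes: int = 4, width: int = 4, **overrides) -> "NetworkSpec":
        """Same topology with filter banks (w, w, 2w, 2w, 2w, 4w) and fc1 = 16w."""
        return cls(
            n_classes=n_classes,
            conv_filters=(width, width, 2 * width, 2 * width, 2 * width, 4 * width),
            fc1_units=16 * width,
            **overrides,
        )

    @property
    def flatten_length(self) -> int:
        return (self.input_shape[0] // 4) * self.input_shape[1] * self.conv_filters[5]


def lr_schedule(epoch: int, spec: NetworkSpec) -> float:
    """Learning rate halved every ``lr_half_life`` epochs: lr0 * 0.5^(epoch // half_life)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return spec.lr0 * 0.5 ** (epoch // spec.lr_half_life)


@dataclass
class LayerShapeReport:
    """Ordered (layer name, output size, units) rows for auditing the architecture."""

    rows: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.rows)

    def output_sizes(self) -> dict:
        return {name: size for name, size, _ in self.rows}

    def __str__(self) -> str:
        lines = [f"{name:35s} {str(size):12s} {units if units else '':>6}" for name, size, units in self.rows]
        return "\n".join(lines)


_LAYER_NAMES = [
    "First Convolutional Layer",
    "Second Convolutional Layer",
    "Third Convolutional Layer",
    "Fourth Convolutional Layer",
    "Fifth Convolutional Layer",
    "Sixth Convolutional Layer",
]


class EmotionNet:
    """The network itself: explicit forward/backward over the numpy layers."""

    def __init__(self, spec: NetworkSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        kh, kw = spec.kernel
        f = spec.conv_filters
        self.convs = [Conv2D(1 if i == 0 else f[i - 1], f[i], kh, kw, rng, dtype) for i in range(6)]
        self.bns = {i: BatchNorm(f[i - 1], axes=(0, 2, 3), dtype=dtype) for i in spec.batchnorm_at if i != "fc1"}
        self.drops = {
            i: Dropout(spec.dropout_keep, structured=True) for i in spec.dropout_at if i != "fc1"
        }
        self.relus = [ReLU() for _ in range(6)]
        self.pool1, self.pool2 = MaxPoolTime(), MaxPoolTime()
        self.projs = {}
        for src, dst in spec.residual_links:
            if f[src - 1] != f[dst - 1]:
                self.projs[(src, dst)] = Conv2D(f[src - 1], f[dst - 1], 1, 1, rng, dtype)
        self.fc1 = Dense(spec.flatten_length, spec.fc1_units, rng, dtype)
        self.bn_fc = BatchNorm(spec.fc1_units, axes=(0,), dtype=dtype) if "fc1" in spec.batchnorm_at else None
        self.relu_fc = ReLU()
        self.drop_fc = Dropout(spec.dropout_keep) if "fc1" in spec.dropout_at else None
        self.fc2 = Dense(spec.fc1_units, spec.n_classes, rng, dtype)
        self.target_activations = None  # conv6 post-ReLU maps from the last forward
        self.target_gradients = None

    @property
    def n_classes(self) -> int:
        return self.spec.n_classes

    # -- parameter bookkeeping ------------------------------------------------
    def _layers(self):
        named = {f"conv{i + 1}": c for i, c in enumerate(self.convs)}
        named.update({f"bn{i}": bn for i, bn in self.bns.items()})
        named.update({f"proj{src}_{dst}": p for (src, dst), p in self.projs.items()})
        named["fc1"] = self.fc1
        named["fc2"] = self.fc2
        if self.bn_fc is not None:
            named["bn_fc"] = self.bn_fc
        return named

    def parameters(self) -> dict:
        return {
            f"{lname}.{pname}": arr
            for lname, layer in self._layers().items()
            for pname, arr in layer.params.items()
        }

    def gradients(self) -> dict:
        return {
            f"{lname}.{pname}": arr
            for lname, layer in self._layers().items()
            for pname, arr in layer.grads.items()
        }

    def weight_parameters(self) -> dict:
        """Conv/dense weight matrices only — the L2-penalised subset."""
        return {
            f"{lname}.W": layer.params["W"]
            for lname, layer in self._layers().items()
            if "W" in getattr(layer, "weight_names", ())
        }

    # -- forward / backward ---------------------------------------------------
    def _conv_block(self, i: int, x: np.ndarray, skip: np.ndarray | None, train: bool, rng) -> np.ndarray:
        """conv -> [+residual] -> [BN] -> ReLU -> [dropout]; i is 1-based."""
        z = self.convs[i - 1].forward(x)
        if skip is not None:
            z = z + skip
        if i in self.bns:
            z = self.bns[i].forward(z, train)
        a = self.relus[i - 1].forward(z)
        if i in self.drops:
            a = self.drops[i].forward(a, train, rng)
        return a

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        """Logits for a batch of images shaped (N, 1, time, channels)."""
        spec = self.spec
        a1 = self._conv_block(1, x, None, train, rng)
        a2 = self._conv_block(2, a1, None, train, rng)
        skip13 = self.projs[(1, 3)].forward(a1) if (1, 3) in self.projs else a1
        a3 = self._conv_block(3, a2, skip13 if (1, 3) in _links(spec) else None, train, rng)
        p1 = self.pool1.forward(a3)
        a4 = self._conv_block(4, p1, None, train, rng)
        a5 = self._conv_block(5, a4, None, train, rng)
        skip46 = self.projs[(4, 6)].forward(a4) if (4, 6) in self.projs else a4
        # conv6 output (post-ReLU) is the Grad-CAM target layer
        z6 = self.convs[5].forward(a5)
        if (4, 6) in _links(spec):
            z6 = z6 + skip46
        a6 = self.relus[5].forward(z6)
        self.target_activations = a6
        a6d = self.drops[6].forward(a6, train, rng) if 6 in self.drops else a6
        p2 = self.pool2.forward(a6d)
        flat = p2.reshape(p2.shape[0], -1)
        self._flat_shape = p2.shape
        g = self.fc1.forward(flat)
        if self.bn_fc is not None:
            g = self.bn_fc.forward(g, train)
        g = self.relu_fc.forward(g)
        if self.drop_fc is not None:
            g = self.drop_fc.forward(g, train, rng)
        return self.fc2.forward(g)

    def backward(self, dlogits: np.ndarray) -> None:
        """Backprop from logit gradients; fills layer ``grads`` and the target-layer gradient."""
        spec = self.spec
        d = self.fc2.backward(dlogits)
        if self.drop_fc is not None:
            d = self.drop_fc.backward(d)
        d = self.relu_fc.backward(d)
        if self.bn_fc is not None:
            d = self.bn_fc.backward(d)
        d = self.fc1.backward(d)
        d = d.reshape(self._flat_shape)
        d = self.pool2.backward(d)
        if 6 in self.drops:
            d = self.drops[6].backward(d)
        self.target_gradients = d  # grad w.r.t. a6, the target-layer activations
        d = self.relus[5].backward(d)  # grad w.r.t. z6 (pre-activation)
        dskip46 = d if (4, 6) in _links(spec) else None
        d = self.convs[5].backward(d)  # -> grad w.r.t. a5
        if dskip46 is not None and (4, 6) in self.projs:
            dskip46 = self.projs[(4, 6)].backward(dskip46)
        d = self._conv_block_backward(5, d)  # -> grad w.r.t. a4
        if dskip46 is not None:
            d = d + dskip46
        d = self._conv_block_backward(4, d)  # -> grad w.r.t. p1
        d = self.pool1.backward(d)  # -> grad w.r.t. a3
        d, dskip13 = self._block3_backward(d)  # -> grad w.r.t. a2 (+ skip to a1)
        d = self._conv_block_backward(2, d)  # -> grad w.r.t. a1
        if dskip13 is not None:
            d = d + dskip13
        d = self._conv_block_backward(1, d)  # -> grad w.r.t. input
        return d

    def _conv_block_backward(self, i: int, dout: np.ndarray) -> np.ndarray:
        if i in self.drops:
            dout = self.drops[i].backward(dout)
        dout = self.relus[i - 1].backward(dout)
        if i in self.bns:
            dout = self.bns[i].backward(dout)
        return self.convs[i - 1].backward(dout)

    def _block3_backward(self, dout: np.ndarray):
        spec = self.spec
        if 3 in self.drops:
            dout = self.drops[3].backward(dout)
        dout = self.relus[2].backward(dout)
        if 3 in self.bns:
            dout = self.bns[3].backward(dout)
        dskip = None
        if (1, 3) in _links(spec):
            dskip = dout
            if (1, 3) in self.projs:
                dskip = self.projs[(1, 3)].backward(dskip)
        return self.convs[2].backward(dout), dskip

    # -- Grad-CAM target-layer protocol --------------------------------------
    def target_forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Inference forward; returns (target activations (N, K, H, W), logits)."""
        logits = self.forward(x, train=False)
        return self.target_activations, logits

    def target_backward(self, class_idx: np.ndarray) -> np.ndarray:
        """Gradient of each sample's class logit w.r.t. the target activations.

        Must be called right after :meth:`target_forward`; ``class_idx`` is one
        class index per sample.
        """
        n = self.target_activations.shape[0]
        dlogits = np.zeros((n, self.spec.n_classes), dtype=self.dtype)
        dlogits[np.arange(n), np.asarray(class_idx)] = 1.0
        self.backward(dlogits)
        return self.target_gradients

    def head_forward(self, a6: np.ndarray) -> np.ndarray:
        """Logits from given target-layer activations (inference mode head only)."""
        p2 = MaxPoolTime().forward(a6)
        flat = p2.reshape(p2.shape[0], -1)
        g = flat @ self.fc1.W.T + self.fc1.b
        if self.bn_fc is not None:
            g = self.bn_fc.gamma * (g - self.bn_fc.running_mean) / np.sqrt(
                self.bn_fc.running_var + self.bn_fc.eps
            ) + self.bn_fc.beta
        g = np.maximum(g, 0.0)
        return g @ self.fc2.W.T + self.fc2.b


def _links(spec: NetworkSpec):
    return tuple(tuple(l) for l in spec.residual_links)


def shape_report(spec: NetworkSpec) -> LayerShapeReport:
    """Layer-by-layer output sizes implied by the spec (time x channels)."""
    h, w = spec.input_shape
    rows = [("Input", (h, w), None)]
    for i, name in enumerate(_LAYER_NAMES):
        rows.append((name, (h, w), spec.conv_filters[i]))
        if i == 2:
            h //= 2
            rows.append(("First Max Pooling Layer", (h, w), None))
    h //= 2
    rows.append(("Second Max Pooling Layer", (h, w), None))
    rows.append(("Flatten Layer", (spec.flatten_length,), None))
    rows.append(("First Fully Connected Layer", (spec.fc1_units,), None))
    rows.append(("Second Fully Connected Layer", (spec.n_classes,), None))
    return LayerShapeReport(rows=rows)


def build_network(spec: NetworkSpec, seed: int = 0, dtype=np.float32) -> tuple[EmotionNet, LayerShapeReport]:
    """Instantiate the network and verify a real forward pass matches the report."""
    net = EmotionNet(spec, seed=seed, dtype=dtype)
    report = shape_report(spec)
    x = np.zeros((1, 1, *spec.input_shape), dtype=dtype)
    acts, logits = net.target_forward(x)
    expected_target = (spec.conv_filters[5], spec.input_shape[0] // 2, spec.input_shape[1])
    if acts.shape[1:] != expected_target:
        raise ValueError(
            f"target-layer shape {acts.shape[1:]} does not match the report's {expected_target}"
        )
    if logits.shape[1] != spec.n_classes:
        raise ValueError(f"logit length {logits.shape[1]} != n_classes {spec.n_classes}")
    return net, report


@dataclass
class TrainedModel:
    """A fitted network plus its spec, per-epoch history and the seed used."""

    net: EmotionNet
    spec: NetworkSpec
    history: list
    rng_seed: int


def _to_images(X: np.ndarray, dtype) -> np.ndarray:
    """(n, channels, time) windows -> (n, 1, time, channels) images."""
    X = np.asarray(X)
    return np.ascontiguousarray(X.transpose(0, 2, 1))[:, None, :, :].astype(dtype)


def train(
    net: EmotionNet,
    X: np.ndarray,
    y: np.ndarray,
    spec: NetworkSpec | None = None,
    seed: int = 0,
    epochs: int | None = None,
    verbose: bool = False,
) -> TrainedModel:
    """Fit with Adam on softmax cross-entropy + L2 weight decay.

    Deterministic under a fixed seed on a fixed platform: the seed drives the
    shuffle order and every dropout mask.
    """
    spec = spec or net.spec
    y = np.asarray(y, dtype=np.int64)
    if X.shape[0] == 0:
        raise ValueError("training set is empty")
    if y.min() < 0 or y.max() >= spec.n_classes:
        raise ValueError(f"labels must lie in [0, {spec.n_classes}), got range [{y.min()}, {y.max()}]")
    n_epochs = spec.epochs if epochs is None else epochs
    xin = _to_images(X, net.dtype)
    rng = np.random.default_rng(seed)
    opt = Adam(net.parameters())
    weight_keys = set(net.weight_parameters())
    history = []
    n = xin.shape[0]
    for epoch in range(n_epochs):
        lr = lr_schedule(epoch, spec)
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            xb, yb = xin[idx], y[idx]
            logits = net.forward(xb, train=True, rng=rng)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            net.backward(dlogits)
            grads = net.gradients()
            if spec.l2_coeff:
                params = net.parameters()
                for k in weight_keys:
                    loss += spec.l2_coeff * float(np.sum(params[k].astype(np.float64) ** 2))
                    grads[k] = grads[k] + 2.0 * spec.l2_coeff * params[k]
            opt.step(grads, lr)
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == yb).sum())
        history.append({"epoch": epoch, "lr": lr, "loss": float(np.mean(losses)), "accuracy": correct / n})
        if verbose:
            print(f"epoch {epoch:3d}  lr {lr:.2e}  loss {history[-1]['loss']:.4f}  acc {history[-1]['accuracy']:.3f}")
    return TrainedModel(net=net, spec=spec, history=history, rng_seed=seed)


def predict(model: TrainedModel | EmotionNet, X: np.ndarray, batch_size: int | None = None):
    """Class probabilities and argmax labels for (n, channels, time) windows."""
    net = model.net if isinstance(model, TrainedModel) else model
    spec = net.spec
    if X.shape[1:] != (spec.input_shape[1], spec.input_shape[0]):
        raise ValueError(
            f"window shape {X.shape[1:]} does not match spec input (channels, time) = "
            f"{(spec.input_shape[1], spec.input_shape[0])}"
        )
    xin = _to_images(X, net.dtype)
    bs = batch_size or spec.batch_size
    probs = np.concatenate(
        [softmax(net.forward(xin[i : i + bs], train=False)) for i in range(0, xin.shape[0], bs)]
    )
    return probs, probs.argmax(axis=1)


class GapHeadNet:
    """A small CAM-compatible reference network: conv stack -> GAP -> linear head.

    With this head the class activation map has the closed form
    ReLU(sum_k w_ck A^k); it exists to cross-check the gradient-based attribution
    machinery against that closed form.
    """

    def __init__(self, n_maps: int = 4, n_classes: int = 2, seed: int = 0, input_shape=(8, 6), dtype=np.float64):
        rng = np.random.default_rng(seed)
        self.conv = Conv2D(1, n_maps, 3, 3, rng, dtype)
        self.relu = ReLU()
        self.head = Dense(n_maps, n_classes, rng, dtype)
        self.n_classes = n_classes
        self.dtype = dtype
        self.target_activations = None

    def target_forward(self, x: np.ndarray):
        a = self.relu.forward(self.conv.forward(x))
        self.target_activations = a
        gap = a.mean(axis=(2, 3))
        return a, self.head.forward(gap)

    def target_backward(self, class_idx: np.ndarray) -> np.ndarray:
        a = self.target_activations
        n, k, h, w = a.shape
        # d logit_c / d A_ijk = w_ck / (H*W), independent of position
        wsel = self.head.W[np.asarray(class_idx)]  # (n, k)
        return np.broadcast_to(wsel[:, :, None, None], a.shape) / (h * w)
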