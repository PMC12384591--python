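"""Model/Results facade over the window classifier and attribution pipeline.

``EmotionClassifier`` holds preprocessed windows and a network specification;
``fit`` trains the CNN and returns an ``EmotionClassifierResults`` carrying the
trained network, training history, and the attribution methods (class activation
maps, per-electrode contribution scores, channel selection, subset stability).
"""

from __future__ import annotations

import numpy as np

from . import attribution, gradcam, pipeline, preprocess
from .attribution import DEFAULT_THRESHOLDS
from .io import EEGTrial, LabelScheme, MontageMap
from .nn import EmotionNet, NetworkSpec, predict, train
from .synth import PlantSpec, generate_dataset


class EmotionClassifier:
    """EEG emotion classifier over fixed-length windows.

    Parameters
    ----------
    X : ndarray, shape (n_windows, 32, 128)
        Preprocessed (baseline-corrected) windows, channels x time.
    y : ndarray of int
        Class indices under ``scheme.class_names``.
    scheme : LabelScheme
        The labelling task (arousal, valence or quaternary).
    spec : NetworkSpec, optional
        Defaults to the canonical architecture with ``n_classes`` taken from the
        scheme.
    """

    def __init__(self, X, y, scheme: LabelScheme, spec: NetworkSpec | None = None,
                 montage: MontageMap | None = None):
        self.X = np.asarray(X)
        self.y = np.asarray(y, dtype=np.int64)
        if self.X.ndim != 3 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be (n_windows, channels, time) aligned with y")
        self.scheme = scheme
        self.spec = spec or NetworkSpec.canonical(n_classes=scheme.n_classes)
        if self.spec.n_classes != scheme.n_classes:
            raise ValueError(
                f"spec has {self.spec.n_classes} classes but task {scheme.task!r} needs {scheme.n_classes}"
            )
        self.montage = montage or MontageMap.default()

    @classmethod
    def from_trials(cls, trials: list[EEGTrial], scheme: LabelScheme,
                    spec: NetworkSpec | None = None, **kw) -> "EmotionClassifier":
        """Baseline-correct and window raw trials, then build the model."""
        X, y, _ = preprocess.trials_to_arrays(trials, scheme)
        return cls(X, y, scheme, spec, **kw)

    @classmethod
    def from_synthetic(cls, plant: PlantSpec, n_per_class: int, task: str = "quaternary",
                       spec: NetworkSpec | None = None, **kw) -> "EmotionClassifier":
        """Generate a planted-signal dataset and build the model from it."""
        ds = generate_dataset(plant, n_per_class)
        return cls.from_trials(ds.trials, LabelScheme(task), spec, **kw)

    def fit(self, seed: int = 0, epochs: int | None = None, verbose: bool = False) -> "EmotionClassifierResults":
        net = EmotionNet(self.spec, seed=seed)
        trained = train(net, self.X, self.y, self.spec, seed=seed, epochs=epochs, verbose=verbose)
        return EmotionClassifierResults(self, trained)

    def cross_validate(self, k: int = 10, seed: int = 0, epochs: int | None = None,
                       groups=None, verbose: bool = False) -> pipeline.CVReport:
        """K-fold CV: a fresh network per fold, held-out window accuracy in %."""
        return pipeline.cross_validate(
            self.X, self.y, self.spec, k=k, seed=seed, epochs=epochs,
            task=self.scheme.task, groups=groups, verbose=verbose,
        )


class EmotionClassifierResults:
    """Estimates and diagnostics from a fitted :class:`EmotionClassifier`."""

    def __init__(self, model: EmotionClassifier, trained):
        self.model = model
        self.trained = trained
        self.net = trained.net
        self.history = trained.history

    # -- prediction -----------------------------------------------------------
    def predict(self, X=None):
        """(probabilities, class indices) for given windows (default: training set)."""
        X = self.model.X if X is None else np.asarray(X)
        return predict(self.net, X)

    def accuracy(self, X=None, y=None) -> float:
        """Top-1 accuracy in %, evaluated in inference mode."""
        X = self.model.X if X is None else np.asarray(X)
        y = self.model.y if y is None else np.asarray(y)
        _, labels = predict(self.net, X)
        return 100.0 * float((labels == y).mean())

    # -- attribution ----------------------------------------------------------
    def activation_maps(self, X=None, classes="true") -> np.ndarray:
        """Grad-CAM heatmaps (n, time, channels) for each window.

        ``classes`` is ``"true"`` (default, needed for per-category averages),
        ``"predicted"``, or an explicit array/int.
        """
        X = self.model.X if X is None else np.asarray(X)
        if isinstance(classes, str) and classes == "true":
            if X.shape[0] != self.model.y.shape[0]:
                raise ValueError("true-class maps for external windows require explicit classes")
            classes = self.model.y
        return gradcam.gradcam_batch(self.net, X, classes=classes)

    def channel_vectors(self, X=None, classes="true") -> np.ndarray:
        """Per-window per-electrode mean activation, shape (n, 32)."""
        return self.activation_maps(X, classes).mean(axis=1)

    def contributions(self, classes="true") -> dict:
        """Per-class normalized contribution scores: {class name: ContributionVector}."""
        vecs = self.channel_vectors(classes=classes)
        per_class = attribution.class_contributions(vecs, self.model.y)
        names = self.model.scheme.class_names
        return {names[c]: cv for c, cv in per_class.items()}

    def task_contribution(self, classes="true") -> attribution.ContributionVector:
        vecs = self.channel_vectors(classes=classes)
        return attribution.task_contribution(vecs, self.model.y)

    def select_channels(self, threshold: float | None = None) -> attribution.ChannelSubset:
        """High-contribution electrodes for this task (strict > threshold)."""
        if threshold is None:
            threshold = DEFAULT_THRESHOLDS[self.model.scheme.task]
        return attribution.select_channels(self.task_contribution(), threshold, self.model.montage)

    def subset_stability(self, sizes, seed: int = 0, threshold: float | None = None) -> attribution.StabilityReport:
        if threshold is None:
            threshold = DEFAULT_THRESHOLDS[self.model.scheme.task]
        vecs = self.channel_vectors()
        return attribution.subset_stability(
            vecs, self.model.y, sizes, seed=seed, threshold=threshold, montage=self.model.montage
        )

    # -- reporting ------------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary: architecture, training run, accuracy, top electrodes."""
        spec = self.model.spec
        tc = self.task_contribution()
        top = np.argsort(-tc.scores)[:8]
        montage = self.model.montage
        lines = [
            "EEG emotion classifier (2D CNN + Grad-CAM attribution)",
            "=" * 56,
            f"task:            {self.model.scheme.task} ({spec.n_classes} classes)",
            f"windows:         {self.model.X.shape[0]} of shape "
            f"{self.model.X.shape[1]}x{self.model.X.shape[2]} (channels x time)",
            f"conv filters:    {list(spec.conv_filters)}  fc1: {spec.fc1_units}",
            f"epochs run:      {len(self.history)}  final loss: {self.history[-1]['loss']:.4f}",
            f"accuracy:        {self.accuracy():.2f} % (training windows, inference mode)",
            "top electrodes:  " + ", ".join(
                f"{montage.name(i)} ({tc.scores[i]:.2f})" for i in top
            ),
        ]
        return "\n".join(lines)

    def plot_contributions(self, ax=None):
        """Bar chart of per-class normalized contribution scores by electrode."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(12, 4))
        names = self.model.montage.names
        xs = np.arange(len(names))
        per_class = self.contributions()
        width = 0.8 / max(len(per_class), 1)
        for i, (label, cv) in enumerate(per_class.items()):
            ax.bar(xs + i * width, cv.scores, width=width, label=str(label))
        ax.set_xticks(xs + 0.4, names, rotation=90)
        ax.set_ylabel("Normalized Contribution Score")
        ax.legend()
        return ax
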