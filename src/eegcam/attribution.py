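"""Normalized per-electrode contribution scores, thresholded channel selection,
and subset-stability analysis.

A class activation map scores every (time, channel) cell; averaging over time
gives one importance value per electrode and window. Per class, these are
averaged over that class's windows and min-max scaled to [0, 1] — the Normalized
Contribution Score. Electrodes scoring above a task-dependent threshold (0.5 for
quaternary and valence, 0.6 for arousal) form the selected subset. Stability is
probed by recomputing scores on random sample subsets and correlating (Pearson)
each subset's score vector with the full-data vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import N_EEG_CHANNELS, MontageMap

#: Per-task selection thresholds used in the published analysis.
DEFAULT_THRESHOLDS = {"quaternary": 0.5, "valence": 0.5, "arousal": 0.6}


@dataclass
class ContributionVector:
    """32 per-channel importance scores in [0, 1] for one class or task."""

    scores: np.ndarray
    label: str = ""
    n_samples_used: int = 0
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (N_EEG_CHANNELS,):
            raise ValueError(f"scores must have shape (32,), got {self.scores.shape}")


@dataclass
class ChannelSubset:
    """Electrode names selected by thresholding a contribution vector."""

    channels: tuple[str, ...]
    threshold: float
    label: str = ""

    def __len__(self) -> int:
        return len(self.channels)

    def __contains__(self, name: str) -> bool:
        return name in self.channels


@dataclass
class SubsetRow:
    subset_size: int
    channels: tuple[str, ...]
    pcc: float


@dataclass
class StabilityReport:
    rows: list[SubsetRow] = field(default_factory=list)
    label: str = ""

    def __iter__(self):
        return iter(self.rows)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "subset_size": [r.subset_size for r in self.rows],
                "channels": [", ".join(r.channels) for r in self.rows],
                "pcc": [r.pcc for r in self.rows],
            }
        )


def channel_means(cam: np.ndarray) -> np.ndarray:
    """Mean over time of a (time, channels) activation map -> (32,) vector."""
    cam = np.asarray(cam)
    if cam.ndim != 2 or cam.shape[1] != N_EEG_CHANNELS:
        raise ValueError(f"expected a (time, {N_EEG_CHANNELS}) map, got shape {cam.shape}")
    return cam.mean(axis=0)


def aggregate(vectors: np.ndarray, labels: np.ndarray, classes=None) -> dict:
    """Per-class mean of per-sample channel vectors.

    ``classes`` fixes which labels must be present (raises if one has no
    samples); by default the classes found in ``labels`` are used.
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    labels = np.asarray(labels)
    if vectors.ndim != 2 or vectors.shape[0] != labels.shape[0]:
        raise ValueError("vectors must be (n_samples, n_channels) aligned with labels")
    if classes is None:
        classes = sorted(np.unique(labels).tolist())
    out = {}
    for cls in classes:
        mask = labels == cls
        if not mask.any():
            raise ValueError(f"class {cls!r} has zero samples")
        out[cls] = vectors[mask].mean(axis=0)
    return out


def normalize(raw: np.ndarray, label: str = "", n_samples: int = 0) -> ContributionVector:
    """Min-max scale a raw mean vector to [0, 1].

    A constant input has no contrast to scale; by convention it maps to all
    zeros with ``degenerate=True`` rather than raising.
    """
    raw = np.asarray(raw, dtype=np.float64)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return ContributionVector(np.zeros_like(raw), label=label, n_samples_used=n_samples, degenerate=True)
    return ContributionVector((raw - lo) / (hi - lo), label=label, n_samples_used=n_samples)


def select_channels(
    vector: ContributionVector, threshold: float, montage: MontageMap | None = None
) -> ChannelSubset:
    """Electrodes whose score strictly exceeds the threshold, in montage order."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    montage = montage or MontageMap.default()
    names = tuple(montage.name(i) for i in range(N_EEG_CHANNELS) if vector.scores[i] > threshold)
    return ChannelSubset(channels=names, threshold=threshold, label=vector.label)


def pearson(v1: np.ndarray, v2: np.ndarray) -> float:
    """Pearson correlation coefficient; requires equal lengths >= 2 and nonzero variance."""
    v1 = np.asarray(v1, dtype=np.float64)
    v2 = np.asarray(v2, dtype=np.float64)
    if v1.shape != v2.shape or v1.ndim != 1 or v1.size < 2:
        raise ValueError("inputs must be equal-length 1-D vectors of length >= 2")
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    return float(stats.pearsonr(v1, v2).statistic)


def class_contributions(vectors: np.ndarray, labels: np.ndarray, classes=None) -> dict:
    """aggregate -> normalize per class; returns {class: ContributionVector}."""
    means = aggregate(vectors, labels, classes)
    labels = np.asarray(labels)
    return {
        cls: normalize(raw, label=str(cls), n_samples=int((labels == cls).sum()))
        for cls, raw in means.items()
    }


def task_contribution(vectors: np.ndarray, labels: np.ndarray, classes=None) -> ContributionVector:
    """One task-level vector: per-class normalized scores averaged over classes,
    then re-scaled to [0, 1]."""
    per_class = class_contributions(vectors, labels, classes)
    pooled = np.mean([cv.scores for cv in per_class.values()], axis=0)
    return normalize(pooled, label="task", n_samples=int(np.asarray(labels).shape[0]))


def _stacked_scores(vectors: np.ndarray, labels: np.ndarray, classes) -> np.ndarray:
    """Per-class normalized score vectors stacked into one long vector."""
    per_class = class_contributions(vectors, labels, classes)
    return np.concatenate([per_class[c].scores for c in classes])


def _union_selection(vectors: np.ndarray, labels: np.ndarray, classes, threshold: float,
                     montage: MontageMap) -> tuple[str, ...]:
    """Channels exceeding the threshold in any class's normalized vector."""
    per_class = class_contributions(vectors, labels, classes)
    keep = np.zeros(N_EEG_CHANNELS, dtype=bool)
    for cv in per_class.values():
        keep |= cv.scores > threshold
    return tuple(montage.name(i) for i in range(N_EEG_CHANNELS) if keep[i])


def subset_stability(
    vectors: np.ndarray,
    labels: np.ndarray,
    sizes,
    seed: int = 0,
    threshold: float = 0.5,
    montage: MontageMap | None = None,
) -> StabilityReport:
    """Recompute contributions on random subsets and correlate with the full data.

    For each size, samples are drawn without replacement (seeded) and the
    per-class pipeline (aggregate -> normalize -> select) is rerun on the
    subset. The report lists the union over classes of the selected
    high-contribution channels and the Pearson correlation between the
    subset's stacked per-class score vectors and the full-data ones. The final
    row is the full dataset itself (PCC = 1 by construction).
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    labels = np.asarray(labels)
    n = vectors.shape[0]
    sizes = sorted(int(s) for s in sizes)
    if sizes and sizes[-1] > n:
        raise ValueError(f"subset size {sizes[-1]} exceeds population {n}")
    montage = montage or MontageMap.default()
    classes = sorted(np.unique(labels).tolist())
    full = _stacked_scores(vectors, labels, classes)
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        idx = rng.choice(n, size=size, replace=False)
        rows.append(
            SubsetRow(
                subset_size=size,
                channels=_union_selection(vectors[idx], labels[idx], classes, threshold, montage),
                pcc=pearson(_stacked_scores(vectors[idx], labels[idx], classes), full),
            )
        )
    rows.append(
        SubsetRow(
            subset_size=n,
            channels=_union_selection(vectors, labels, classes, threshold, montage),
            pcc=1.0,
        )
    )
    return StabilityReport(rows=rows)
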