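"""Baseline-template subtraction and fixed-length windowing.

The correction has three steps: segment the pre-stimulus baseline into N
consecutive channels x L blocks, average them element-wise into a template, and
subtract that template from every channels x L block of the stimulus region. For
the native trial layout (384 baseline samples, L = 128) this gives N = 3 and 60
non-overlapping stimulus windows of 32 x 128, each inheriting the trial's label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EEGTrial, LabelScheme, label_trial

WINDOW_LEN = 128


@dataclass
class BaselineTemplate:
    """Element-wise mean of the N consecutive baseline segments, shape (C, L)."""

    data: np.ndarray
    n_segments_used: int


@dataclass
class Window:
    """One preprocessed C x L segment carrying its trial's class label."""

    data: np.ndarray
    label: str
    label_index: int
    trial_id: str = ""
    subject_id: str = ""
    window_index: int = 0


def compute_baseline_template(baseline: np.ndarray, seg_len: int = WINDOW_LEN) -> BaselineTemplate:
    """Average the baseline's consecutive C x seg_len segments into one template."""
    baseline = np.asarray(baseline, dtype=np.float64)
    n_channels, n_samples = baseline.shape
    if n_samples % seg_len:
        raise ValueError(f"baseline length {n_samples} is not divisible by segment length {seg_len}")
    n_seg = n_samples // seg_len
    template = baseline.reshape(n_channels, n_seg, seg_len).mean(axis=1)
    return BaselineTemplate(data=template, n_segments_used=n_seg)


def remove_baseline(stimulus: np.ndarray, template: BaselineTemplate) -> np.ndarray:
    """Subtract the template from each consecutive C x L block of the stimulus."""
    stimulus = np.asarray(stimulus, dtype=np.float64)
    n_channels, n_samples = stimulus.shape
    tc, seg_len = template.data.shape
    if tc != n_channels:
        raise ValueError(f"template has {tc} channels, stimulus has {n_channels}")
    if n_samples % seg_len:
        raise ValueError(f"stimulus length {n_samples} is not divisible by segment length {seg_len}")
    n_win = n_samples // seg_len
    out = stimulus.reshape(n_channels, n_win, seg_len) - template.data[:, None, :]
    return out.reshape(n_channels, n_samples)


def make_windows(trial: EEGTrial, scheme: LabelScheme, seg_len: int = WINDOW_LEN) -> list[Window]:
    """Baseline-correct a trial and slice it into labelled non-overlapping windows."""
    template = compute_baseline_template(trial.baseline, seg_len)
    corrected = remove_baseline(trial.stimulus, template)
    label = label_trial(trial, scheme)
    idx = scheme.class_names.index(label)
    n_win = corrected.shape[1] // seg_len
    return [
        Window(
            data=corrected[:, k * seg_len : (k + 1) * seg_len],
            label=label,
            label_index=idx,
            trial_id=trial.trial_id,
            subject_id=trial.subject_id,
            window_index=k,
        )
        for k in range(n_win)
    ]


def windows_to_arrays(windows: list[Window]) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into ``X`` (n, C, L) and integer labels ``y`` (n,)."""
    X = np.stack([w.data for w in windows])
    y = np.array([w.label_index for w in windows], dtype=np.int64)
    return X, y


def trials_to_arrays(trials: list[EEGTrial], scheme: LabelScheme, seg_len: int = WINDOW_LEN):
    """Preprocess many trials at once; returns (X, y, windows)."""
    windows: list[Window] = []
    for t in trials:
        windows.extend(make_windows(t, scheme, seg_len))
    X, y = windows_to_arrays(windows)
    return X, y, windows


def save_windows(path, windows: list[Window], scheme: LabelScheme) -> None:
    """Write a windows container (.npz): data tensor, labels, ids, task."""
    X, y = windows_to_arrays(windows)
    np.savez_compressed(
        path,
        data=X,
        labels=y,
        label_names=np.array(scheme.class_names),
        task=np.array(scheme.task),
        trial_ids=np.array([w.trial_id for w in windows]),
        subject_ids=np.array([w.subject_id for w in windows]),
        window_index=np.array([w.window_index for w in windows]),
    )


def load_windows(path) -> tuple[np.ndarray, np.ndarray, LabelScheme]:
    """Read a windows container; returns (X, y, scheme)."""
    with np.load(path, allow_pickle=False) as z:
        X = z["data"]
        y = z["labels"]
        scheme = LabelScheme(task=str(z["task"]))
    return X, y, scheme
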