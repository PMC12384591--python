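"""Trial containers, rating-threshold labelling, montage mapping and tabular outputs.

The native layout mirrors the preprocessed DEAP release: per subject, 40 trials of
40 channels x 8064 samples at 128 Hz (first 32 channels are EEG, first 384 samples
are the pre-stimulus baseline), plus a 40 x 4 self-rating array on 1-9 scales.
"""

from __future__ import annotations

import csv
import pickle
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

FS = 128
N_EEG_CHANNELS = 32
TRIAL_SAMPLES = 8064
BASELINE_SAMPLES = 384
DEAP_TRIALS_PER_SUBJECT = 40
DEAP_TOTAL_CHANNELS = 40

#: Quadrant class names, ordered (low/high arousal) x (low/high valence).
QUATERNARY_CLASSES = ("LALV", "HALV", "LAHV", "HAHV")
BINARY_CLASSES = ("low", "high")


@dataclass
class EEGTrial:
    """One channels x samples recording with a leading baseline region.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in native units, sampled at 128 Hz.
    n_baseline : int
        Number of leading samples recorded before stimulus onset.
    arousal, valence : float
        Self-assessment ratings on the 1-9 scale.
    subject_id, trial_id : str
        Opaque identifiers carried through the pipeline.
    """

    data: np.ndarray
    n_baseline: int = BASELINE_SAMPLES
    arousal: float = 5.0
    valence: float = 5.0
    subject_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"trial data must be 2-D (channels x samples), got ndim={self.data.ndim}")
        if self.data.shape[1] < self.n_baseline:
            raise ValueError(
                f"trial has {self.data.shape[1]} samples, fewer than n_baseline={self.n_baseline}"
            )
        for name, value in (("arousal", self.arousal), ("valence", self.valence)):
            if not (1.0 <= float(value) <= 9.0):
                raise ValueError(f"{name} rating {value} outside [1, 9]")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def baseline(self) -> np.ndarray:
        """The pre-stimulus region, shape (n_channels, n_baseline)."""
        return self.data[:, : self.n_baseline]

    @property
    def stimulus(self) -> np.ndarray:
        """The stimulus region, shape (n_channels, n_samples - n_baseline)."""
        return self.data[:, self.n_baseline :]


@dataclass(frozen=True)
class LabelScheme:
    """Rating-threshold labelling: <= threshold is "low", > threshold is "high".

    ``task`` is one of ``"arousal"``, ``"valence"`` (binary low/high on that rating)
    or ``"quaternary"`` (joint arousal x valence quadrants).
    """

    task: str = "quaternary"
    threshold: float = 5.0

    _ALIASES = {"arousal-binary": "arousal", "valence-binary": "valence"}

    def __post_init__(self) -> None:
        task = self._ALIASES.get(self.task, self.task)
        object.__setattr__(self, "task", task)
        if task not in ("arousal", "valence", "quaternary"):
            raise ValueError(f"unknown task {self.task!r}")

    @property
    def class_names(self) -> tuple[str, ...]:
        if self.task == "quaternary":
            return QUATERNARY_CLASSES
        return BINARY_CLASSES

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


def label_trial(trial: EEGTrial, scheme: LabelScheme) -> str:
    """Class name for a trial under the scheme's threshold rule."""
    high_a = trial.arousal > scheme.threshold
    high_v = trial.valence > scheme.threshold
    if scheme.task == "arousal":
        return "high" if high_a else "low"
    if scheme.task == "valence":
        return "high" if high_v else "low"
    return ("H" if high_a else "L") + "A" + ("H" if high_v else "L") + "V"


def label_index(trial: EEGTrial, scheme: LabelScheme) -> int:
    """Integer class index of :func:`label_trial` within ``scheme.class_names``."""
    return scheme.class_names.index(label_trial(trial, scheme))


@dataclass(frozen=True)
class MontageMap:
    """Ordered 10-20 electrode names for the 32 channel indices."""

    names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        if len(self.names) != N_EEG_CHANNELS:
            raise ValueError(f"montage must list exactly {N_EEG_CHANNELS} electrodes, got {len(self.names)}")
        if len(set(self.names)) != N_EEG_CHANNELS:
            raise ValueError("montage electrode names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def name(self, index: int) -> str:
        return self.names[index]

    def index(self, name: str) -> int:
        return self.names.index(name)

    @classmethod
    def from_csv(cls, path) -> "MontageMap":
        names: dict[int, str] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                names[int(row["index"])] = row["name"].strip()
        return cls(tuple(names[i] for i in sorted(names)))

    @classmethod
    def default(cls) -> "MontageMap":
        """The channel ordering documented for the preprocessed DEAP release."""
        with resources.as_file(resources.files("eegcam.data") / "deap_montage.csv") as p:
            return cls.from_csv(p)


def _validate_deap_arrays(data: np.ndarray, ratings: np.ndarray) -> None:
    if data.ndim != 3:
        raise ValueError(f"data array must be 3-D (trials x channels x samples), got ndim={data.ndim}")
    n_trials, n_channels, n_samples = data.shape
    if n_trials != DEAP_TRIALS_PER_SUBJECT:
        raise ValueError(f"trial dimension is {n_trials}, expected {DEAP_TRIALS_PER_SUBJECT}")
    if n_channels not in (DEAP_TOTAL_CHANNELS, N_EEG_CHANNELS):
        raise ValueError(
            f"channel dimension is {n_channels}, expected {DEAP_TOTAL_CHANNELS} (raw) or {N_EEG_CHANNELS} (EEG only)"
        )
    if n_samples != TRIAL_SAMPLES:
        raise ValueError(f"sample dimension is {n_samples}, expected {TRIAL_SAMPLES}")
    if ratings.shape[0] != n_trials:
        raise ValueError(f"ratings trial dimension is {ratings.shape[0]}, expected {n_trials}")
    if ratings.ndim != 2 or ratings.shape[1] < 2:
        raise ValueError("ratings array must be 2-D with at least valence and arousal columns")
    if np.any(ratings[:, :2] < 1.0) or np.any(ratings[:, :2] > 9.0):
        bad = ratings[:, :2][(ratings[:, :2] < 1.0) | (ratings[:, :2] > 9.0)][0]
        raise ValueError(f"rating {bad} outside [1, 9]")


def read_deap_subject(path) -> list[EEGTrial]:
    """Read one preprocessed-DEAP per-subject container.

    Accepts the pickled ``{"data": 40x40x8064, "labels": 40x4}`` dict (``.dat``/``.pkl``)
    or an ``.npz`` with the same keys. Only the first 32 (EEG) channels are kept.
    Rating column order follows the DEAP documentation: valence, arousal[, dominance,
    liking].
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            data, ratings = np.asarray(z["data"]), np.asarray(z["labels"])
    else:
        with open(path, "rb") as fh:
            payload = pickle.load(fh, encoding="latin1")
        data, ratings = np.asarray(payload["data"]), np.asarray(payload["labels"])
    _validate_deap_arrays(data, ratings)
    subject = path.stem
    trials = []
    for i in range(data.shape[0]):
        trials.append(
            EEGTrial(
                data=data[i, :N_EEG_CHANNELS, :],
                n_baseline=BASELINE_SAMPLES,
                valence=float(ratings[i, 0]),
                arousal=float(ratings[i, 1]),
                subject_id=subject,
                trial_id=f"{subject}-t{i:02d}",
            )
        )
    return trials


def write_deap_subject(path, trials: list[EEGTrial]) -> None:
    """Write trials in the preprocessed-DEAP per-subject pickle layout.

    Requires exactly 40 trials of 32 x 8064; the 8 peripheral channels are zero-filled.
    """
    if len(trials) != DEAP_TRIALS_PER_SUBJECT:
        raise ValueError(f"DEAP layout requires {DEAP_TRIALS_PER_SUBJECT} trials, got {len(trials)}")
    data = np.zeros((DEAP_TRIALS_PER_SUBJECT, DEAP_TOTAL_CHANNELS, TRIAL_SAMPLES))
    ratings = np.zeros((DEAP_TRIALS_PER_SUBJECT, 4))
    for i, t in enumerate(trials):
        if t.data.shape != (N_EEG_CHANNELS, TRIAL_SAMPLES):
            raise ValueError(f"trial {i} has shape {t.data.shape}, expected (32, 8064)")
        data[i, :N_EEG_CHANNELS] = t.data
        ratings[i, 0] = t.valence
        ratings[i, 1] = t.arousal
        ratings[i, 2:] = 5.0
    with open(path, "wb") as fh:
        pickle.dump({"data": data, "labels": ratings}, fh)


def save_trials(path, trials: list[EEGTrial], montage: MontageMap | None = None, **extra) -> None:
    """Write trials to the generic compressed array container (``.npz``)."""
    n_baseline = {t.n_baseline for t in trials}
    if len(n_baseline) != 1:
        raise ValueError("all trials in one container must share n_baseline")
    montage = montage or MontageMap.default()
    np.savez_compressed(
        path,
        data=np.stack([t.data for t in trials]),
        arousal=np.array([t.arousal for t in trials]),
        valence=np.array([t.valence for t in trials]),
        n_baseline=np.array(n_baseline.pop()),
        subject_ids=np.array([t.subject_id for t in trials]),
        trial_ids=np.array([t.trial_id for t in trials]),
        channel_names=np.array(montage.names),
        **extra,
    )


def load_trials(path) -> list[EEGTrial]:
    """Read trials back from the generic array container; inverse of :func:`save_trials`."""
    with np.load(path, allow_pickle=False) as z:
        n_baseline = int(z["n_baseline"])
        return [
            EEGTrial(
                data=z["data"][i],
                n_baseline=n_baseline,
                arousal=float(z["arousal"][i]),
                valence=float(z["valence"][i]),
                subject_id=str(z["subject_ids"][i]),
                trial_id=str(z["trial_ids"][i]),
            )
            for i in range(z["data"].shape[0])
        ]


def write_contributions(vectors: dict, montage: MontageMap, path) -> None:
    """Write per-class channel contribution scores as CSV.

    ``vectors`` maps class/task label to a length-32 score vector. Rows are channels
    (index, electrode name, one column per class); floats are written with full
    precision so a re-read is bit-exact.
    """
    columns: dict[str, object] = {
        "index": np.arange(N_EEG_CHANNELS),
        "name": list(montage.names),
    }
    for label, vec in vectors.items():
        vec = np.asarray(vec, dtype=np.float64)
        if vec.shape != (N_EEG_CHANNELS,):
            raise ValueError(f"contribution vector for {label!r} has shape {vec.shape}, expected (32,)")
        columns[str(label)] = vec
    df = pd.DataFrame(columns)
    df.to_csv(path, index=False, float_format="%.17g")


def read_contributions(path) -> tuple[dict, MontageMap]:
    """Read a contribution CSV back into ``{label: scores}`` plus its montage."""
    df = pd.read_csv(path, float_precision="round_trip")
    montage = MontageMap(tuple(df["name"]))
    vectors = {
        col: df[col].to_numpy(dtype=np.float64)
        for col in df.columns
        if col not in ("index", "name")
    }
    return vectors, montage
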