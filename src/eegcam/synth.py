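"""Synthetic DEAP-layout EEG with class-discriminative signal planted on known channels.

Each trial is 32 channels x 8064 samples at 128 Hz (3 s baseline + 60 s stimulus).
Class information is carried by band-limited oscillatory power on a chosen channel
subset: the 10 Hz amplitude encodes the arousal level and the 20 Hz amplitude the
valence level, so thresholding the drawn ratings at 5 reproduces the intended
quadrant and a power-based classifier restricted to the planted channels can
separate all four classes. The baseline region never carries class signal, and a
per-channel DC offset shared by baseline and stimulus makes baseline subtraction
demonstrably useful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import (
    BASELINE_SAMPLES,
    FS,
    N_EEG_CHANNELS,
    QUATERNARY_CLASSES,
    TRIAL_SAMPLES,
    EEGTrial,
)

#: Carrier frequencies (Hz) of the planted class effect.
AROUSAL_FREQ = 10.0
VALENCE_FREQ = 20.0

_EFFECT_KINDS = ("oscillation-power", "amplitude")


@dataclass(frozen=True)
class PlantSpec:
    """Where and how strongly class-discriminative signal is planted.

    Parameters
    ----------
    planted_channels : tuple of int
        0-based channel indices (subset of 0..31) that carry the class effect.
    effect_kind : {"oscillation-power", "amplitude"}
        "oscillation-power" adds class-dependent 10/20 Hz sinusoids (the default;
        band power is the canonical EEG feature); "amplitude" adds a class-dependent
        DC shift instead.
    effect_size : float
        Dimensionless multiplier on the effect amplitude, in units of ``noise_sd``.
        0 means no class information anywhere.
    noise_sd : float
        Standard deviation of the white Gaussian background on every channel.
    baseline_offset_sd : float
        SD of the per-channel DC offset shared by baseline and stimulus.
    seed : int
        Root seed; fans out to per-trial substreams.
    """

    planted_channels: tuple[int, ...] = (19, 21)
    effect_kind: str = "oscillation-power"
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline_offset_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        chans = tuple(int(c) for c in self.planted_channels)
        object.__setattr__(self, "planted_channels", chans)
        if not chans:
            raise ValueError("planted_channels must be non-empty")
        if len(set(chans)) != len(chans):
            raise ValueError("planted_channels must be duplicate-free")
        if any(c < 0 or c >= N_EEG_CHANNELS for c in chans):
            raise ValueError(f"planted_channels must lie in 0..{N_EEG_CHANNELS - 1}")
        if self.effect_kind not in _EFFECT_KINDS:
            raise ValueError(f"effect_kind must be one of {_EFFECT_KINDS}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass
class SyntheticDataset:
    trials: list[EEGTrial]
    plant: PlantSpec
    class_balance: dict[str, int] = field(default_factory=dict)


def _draw_rating(rng: np.random.Generator, high: bool) -> float:
    # low ratings are uniform on {1..5}, high on {6..9}: thresholding at 5
    # (<=5 low, >5 high) recovers the intended level deterministically.
    return float(rng.integers(6, 10) if high else rng.integers(1, 6))


def generate_trial(plant: PlantSpec, target_class: str, rng: np.random.Generator) -> EEGTrial:
    """One 32 x 8064 trial of the requested arousal/valence quadrant.

    The 384 baseline samples contain noise plus the per-channel offset only; the
    7680 stimulus samples add the class effect on ``plant.planted_channels``.
    """
    if target_class not in QUATERNARY_CLASSES:
        raise ValueError(f"target_class must be one of {QUATERNARY_CLASSES}, got {target_class!r}")
    high_a = target_class[0] == "H"
    high_v = target_class[2] == "H"

    arousal = _draw_rating(rng, high_a)
    valence = _draw_rating(rng, high_v)
    offsets = rng.normal(0.0, plant.baseline_offset_sd, size=(N_EEG_CHANNELS, 1))
    data = rng.normal(0.0, plant.noise_sd, size=(N_EEG_CHANNELS, TRIAL_SAMPLES)) + offsets

    # distinct, nonzero amplitude per level: every class leaves band power on
    # the planted channels, so class-conditional attribution sees them for all
    # four quadrants; effect_size = 0 still means no oscillation anywhere
    amp_a = plant.effect_size * plant.noise_sd * (1.5 if high_a else 0.5)
    amp_v = plant.effect_size * plant.noise_sd * (1.5 if high_v else 0.5)
    t = np.arange(TRIAL_SAMPLES - BASELINE_SAMPLES) / FS
    chans = list(plant.planted_channels)
    if plant.effect_kind == "oscillation-power":
        # The planted channels split the two affect carriers round-robin:
        # even positions get the 10 Hz arousal code, odd positions the 20 Hz
        # valence code (a single planted channel carries both). Every planted
        # channel is then necessary for the joint task — if each carried the
        # full class code, a classifier could read just one and per-channel
        # attribution of the rest would be unidentifiable. Phases are drawn
        # independently per channel.
        effect = np.zeros((len(chans), t.shape[0]))
        phases = rng.uniform(0.0, 2.0 * np.pi, size=len(chans))
        for pos in range(len(chans)):
            carries_a = len(chans) == 1 or pos % 2 == 0
            carries_v = len(chans) == 1 or pos % 2 == 1
            if carries_a:
                effect[pos] += amp_a * np.sin(2.0 * np.pi * AROUSAL_FREQ * t + phases[pos])
            if carries_v:
                effect[pos] += amp_v * np.sin(2.0 * np.pi * VALENCE_FREQ * t + phases[pos])
    else:  # constant amplitude shift
        effect = np.full((len(chans), t.shape[0]), amp_a + amp_v)
    data[chans, BASELINE_SAMPLES:] += effect

    return EEGTrial(
        data=data,
        n_baseline=BASELINE_SAMPLES,
        arousal=arousal,
        valence=valence,
        subject_id="synthetic",
        trial_id=f"{target_class}",
    )


def generate_dataset(plant: PlantSpec, n_per_class: int) -> SyntheticDataset:
    """``4 * n_per_class`` trials, exactly ``n_per_class`` per quadrant.

    A single root seed fans out to one independent substream per trial, so the
    dataset is bit-reproducible and trials can be generated in any order.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    seeds = np.random.SeedSequence(plant.seed).spawn(4 * n_per_class)
    trials = []
    for j, cls in enumerate(QUATERNARY_CLASSES):
        for i in range(n_per_class):
            rng = np.random.Generator(np.random.PCG64(seeds[j * n_per_class + i]))
            trial = generate_trial(plant, cls, rng)
            trial.trial_id = f"{cls}-{i:03d}"
            trials.append(trial)
    balance = {cls: n_per_class for cls in QUATERNARY_CLASSES}
    return SyntheticDataset(trials=trials, plant=plant, class_balance=balance)
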