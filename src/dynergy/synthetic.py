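"""Synthetic multichannel EEG-like data with controllable class structure.

Each trial is a sum of band-limited oscillatory components shared across
channels (amplitudes set per class and band), scaled per channel by a
region gain and a per-subject channel gain, plus iid Gaussian channel noise.
Band-limiting uses the same DFT-mask filter as the feature extractor, so the
generator's ground-truth band structure is exactly what the features see.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .features import BANDS, band_limit
from .signal_io import (
    DEAP_REGIONS,
    DatasetBundle,
    MultichannelRecording,
    SEED_REGIONS,
    ValidationError,
)

__all__ = [
    "SyntheticConfig",
    "generate_trial",
    "generate_bundle",
    "add_channel_noise",
    "seed_like_config",
    "deap_like_config",
]

# mild regional gain gradient: anterior regions slightly hotter
_REGION_GAIN = {1: 1.15, 2: 1.05, 3: 0.95, 4: 0.85}


def _montage_channels(n_channels: int) -> tuple[list[str], np.ndarray]:
    """Channel names and per-channel region gains for 62- or 32-ch montages."""
    if n_channels == 62:
        table = SEED_REGIONS
    elif n_channels == 32:
        table = DEAP_REGIONS
    else:
        names = [f"CH{i + 1}" for i in range(n_channels)]
        return names, np.ones(n_channels)
    names, gains = [], []
    for region, channels in table.items():
        for ch in channels:
            names.append(ch)
            gains.append(_REGION_GAIN[region])
    return names, np.asarray(gains)


def _default_band_power() -> dict[int, dict[str, float]]:
    base = {"theta": 1.0, "alpha": 1.0, "beta": 0.8, "gamma": 0.6}
    strong = dict(base, gamma=1.2)  # class 1 doubles the gamma amplitude
    return {0: base, 1: strong}


@dataclass
class SyntheticConfig:
    n_subjects: int = 5
    trials_per_subject: int = 20
    n_channels: int = 62
    fs: float = 200.0
    duration_s: float = 60.0
    class_band_power: dict[int, dict[str, float]] = field(
        default_factory=_default_band_power)
    channel_noise_sd: float = 1.0
    subject_effect_sd: float = 0.1
    label_scheme: str = "seed2"
    seed: int = 0

    def __post_init__(self):
        if min(self.n_subjects, self.trials_per_subject,
               self.n_channels) <= 0:
            raise ValidationError("counts must be positive")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValidationError("fs and duration must be positive")
        for cls, powers in self.class_band_power.items():
            for band, amp in powers.items():
                if band not in BANDS:
                    raise ValidationError(f"unknown band {band!r}")
                if amp < 0:
                    raise ValidationError("amplitudes must be nonnegative")
        if self.channel_noise_sd < 0 or self.subject_effect_sd < 0:
            raise ValidationError("noise scales must be nonnegative")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))

    @property
    def classes(self) -> list[int]:
        return sorted(self.class_band_power)


def _subject_gains(cfg: SyntheticConfig, subject_id: int) -> np.ndarray:
    """Per-channel multiplicative gains, fixed per subject."""
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 7919, subject_id]))
    return 1.0 + cfg.subject_effect_sd * rng.standard_normal(cfg.n_channels)


def generate_trial(cfg: SyntheticConfig, class_id: int, subject_id: int,
                   rng: np.random.Generator) -> MultichannelRecording:
    """One trial: shared band-limited components + channel noise."""
    if class_id not in cfg.class_band_power:
        raise ValidationError(f"class {class_id} not in config")
    n = cfg.n_samples
    names, region_gain = _montage_channels(cfg.n_channels)
    common = np.zeros(n)
    for band_name, amp in cfg.class_band_power[class_id].items():
        if amp == 0:
            continue
        raw = rng.standard_normal(n)
        comp = band_limit(raw, BANDS[band_name], cfg.fs)
        sd = comp.std()
        if sd > 0:
            common += amp * comp / sd
    gains = region_gain * _subject_gains(cfg, subject_id)
    data = gains[:, None] * common[None, :]
    if cfg.channel_noise_sd > 0:
        data = data + rng.normal(0.0, cfg.channel_noise_sd,
                                 size=(cfg.n_channels, n))
    return MultichannelRecording(data, cfg.fs, names,
                                 subject_id=subject_id, label=class_id)


def generate_bundle(cfg: SyntheticConfig) -> DatasetBundle:
    """Balanced-class bundle; fully deterministic under ``cfg.seed``."""
    classes = cfg.classes
    recordings, labels, subjects = [], [], []
    root = np.random.SeedSequence([cfg.seed, 104729])
    streams = root.spawn(cfg.n_subjects * cfg.trials_per_subject)
    k = 0
    for subject in range(cfg.n_subjects):
        for t in range(cfg.trials_per_subject):
            cls = classes[t % len(classes)]
            rng = np.random.default_rng(streams[k])
            recordings.append(generate_trial(cfg, cls, subject, rng))
            labels.append(cls)
            subjects.append(subject)
            k += 1
    return DatasetBundle(recordings, np.asarray(labels),
                         np.asarray(subjects), cfg.label_scheme)


def add_channel_noise(rec: MultichannelRecording, sd: float,
                      rng: np.random.Generator) -> MultichannelRecording:
    """Recording plus iid zero-mean Gaussian noise per channel-sample."""
    if sd < 0:
        raise ValidationError("sd must be nonnegative")
    data = rec.data if sd == 0 else rec.data + rng.normal(
        0.0, sd, size=rec.data.shape)
    return MultichannelRecording(data, rec.fs, list(rec.channel_names),
                                 trial_id=rec.trial_id,
                                 subject_id=rec.subject_id, label=rec.label)


def seed_like_config(n_subjects: int = 5, trials_per_subject: int = 20,
                     n_classes: int = 2, seed: int = 0,
                     **overrides) -> SyntheticConfig:
    """62 channels @ 200 Hz, 60-s trials (SEED-shaped)."""
    powers = _default_band_power()
    if n_classes == 3:
        powers[2] = dict(powers[0], gamma=0.9, beta=1.2)
    scheme = "seed2" if n_classes == 2 else "seed3"
    return SyntheticConfig(
        n_subjects=n_subjects, trials_per_subject=trials_per_subject,
        n_channels=62, fs=200.0, duration_s=60.0, class_band_power=powers,
        label_scheme=scheme, seed=seed, **overrides)


def deap_like_config(n_subjects: int = 5, trials_per_subject: int = 20,
                     seed: int = 0, **overrides) -> SyntheticConfig:
    """32 channels @ 128 Hz, 60-s trials (DEAP-shaped), 2 classes."""
    return SyntheticConfig(
        n_subjects=n_subjects, trials_per_subject=trials_per_subject,
        n_channels=32, fs=128.0, duration_s=60.0,
        label_scheme="deap_valence", seed=seed, **overrides)
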