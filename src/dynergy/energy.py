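"""Project multichannel recordings onto a single energy sequence and window it.

The energy sequence is the per-sample weighted cross-channel average.  With
uniform weights it is the plain channel mean; with a regional weighting each
region's coefficient sum is split equally over its channels, so regions with
higher coefficients contribute more.  Averaging over N channels shrinks the
variance of independent per-channel noise by 1/N, which is the point of the
projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import (
    MultichannelRecording,
    RegionWeighting,
    ValidationError,
    normalize_channel,
)

__all__ = [
    "EnergySequence",
    "WindowSpec",
    "channel_weights",
    "energy_sequence",
    "slide_windows",
]


@dataclass
class EnergySequence:
    values: np.ndarray
    fs: float
    weighting: str = "uniform"  # {"uniform", "regional"}

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.isfinite(self.values).all():
            raise ValidationError("energy sequence contains non-finite values")
        if not self.fs > 0:
            raise ValidationError("fs must be positive")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class WindowSpec:
    """Moving-window geometry in seconds."""

    width_s: float = 4.0
    step_s: float = 2.0

    def __post_init__(self):
        if not self.width_s > 0:
            raise ValidationError("window width must be positive")
        if not 0 < self.step_s <= self.width_s:
            raise ValidationError("step must satisfy 0 < step <= width")

    def in_samples(self, fs: float) -> tuple[int, int]:
        width = int(round(self.width_s * fs))
        step = int(round(self.step_s * fs))
        if width < 1 or step < 1:
            raise ValidationError("window shorter than one sample at this fs")
        return width, step

    def n_windows(self, n_samples: int, fs: float) -> int:
        width, step = self.in_samples(fs)
        if n_samples < width:
            raise ValidationError(
                f"signal of {n_samples} samples shorter than one "
                f"{width}-sample window"
            )
        return (n_samples - width) // step + 1


def channel_weights(weighting: RegionWeighting,
                    channel_names: list[str]) -> np.ndarray:
    """Per-channel weights: each region's sum split equally over its channels.

    The returned vector aligns with ``channel_names`` and sums to 1.
    """
    regions = [weighting.region(ch) for ch in channel_names]
    counts: dict[int, int] = {}
    for r in regions:
        counts[r] = counts.get(r, 0) + 1
    for region, total in weighting.region_sum.items():
        if total > 0 and counts.get(region, 0) == 0:
            raise ValidationError(
                f"region {region} has coefficient {total} but no channels"
            )
    w = np.array([weighting.region_sum[r] / counts[r] for r in regions])
    return w


def energy_sequence(rec: MultichannelRecording,
                    weights=None) -> EnergySequence:
    """Weighted per-sample cross-channel average.

    ``weights`` may be None (uniform 1/N), a per-channel vector, or a
    RegionWeighting (resolved against the recording's channel names).
    """
    if weights is None:
        w = np.full(rec.n_channels, 1.0 / rec.n_channels)
        kind = "uniform"
    elif isinstance(weights, RegionWeighting):
        w = channel_weights(weights, rec.channel_names)
        kind = "regional"
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if len(w) != rec.n_channels:
            raise ValidationError(
                f"{len(w)} weights for {rec.n_channels} channels"
            )
        kind = "regional"
    if not np.isfinite(rec.data).all():
        raise ValidationError("recording contains non-finite values")
    return EnergySequence(w @ rec.data, rec.fs, kind)


def slide_windows(es: EnergySequence, spec: WindowSpec) -> list[np.ndarray]:
    """Half-open windows starting at 0, step, 2*step, ...; partials dropped."""
    width, step = spec.in_samples(es.fs)
    n = spec.n_windows(len(es), es.fs)
    return [es.values[k * step: k * step + width] for k in range(n)]
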