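"""Recording / feature-table I/O and montage region-weight configuration.

Formats
-------
* EDF (16-bit, standard header) via the bundled minimal codec.
* CSV recordings: first row = channel names, one column per channel, one row
  per sample.  CSV carries no sampling rate, so ``fs`` must be supplied.
* HDF5 recordings: datasets ``/data`` (channels x samples) and
  ``/channel_names``; ``fs`` stored as a root attribute.
* Montage config: key-value text, ``<channel> = <region id>`` lines plus
  ``region_sum_<id> = <coefficient>`` lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from . import _edf

__all__ = [
    "MultichannelRecording",
    "RegionWeighting",
    "DatasetBundle",
    "read_recording",
    "write_recording",
    "load_region_weighting",
    "region_weighting_preset",
    "write_feature_table",
    "read_feature_table",
    "SEED_REGIONS",
    "DEAP_REGIONS",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


def normalize_channel(name: str) -> str:
    """Case-insensitive, whitespace-insensitive channel key."""
    return "".join(str(name).split()).upper()


@dataclass
class MultichannelRecording:
    """A channels x samples recording with its sampling rate."""

    data: np.ndarray
    fs: float
    channel_names: list[str]
    trial_id: Optional[int] = None
    subject_id: Optional[int] = None
    label: Optional[int] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValidationError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_names)} channel names"
            )
        if not self.fs > 0:
            raise ValidationError("fs must be positive")
        bad = ~np.isfinite(self.data)
        if bad.any():
            ch = self.channel_names[int(np.flatnonzero(bad.any(axis=1))[0])]
            raise ValidationError(f"non-finite values in channel {ch!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def excerpt(self, start_s: float, stop_s: float) -> "MultichannelRecording":
        """Return the [start_s, stop_s) slice as a new recording."""
        i0 = int(round(start_s * self.fs))
        i1 = int(round(stop_s * self.fs))
        if not (0 <= i0 < i1 <= self.n_samples):
            raise ValidationError(
                f"excerpt [{start_s}, {stop_s})s outside recording of "
                f"{self.duration_s:g}s"
            )
        return MultichannelRecording(
            self.data[:, i0:i1], self.fs, list(self.channel_names),
            trial_id=self.trial_id, subject_id=self.subject_id,
            label=self.label,
        )


@dataclass
class RegionWeighting:
    """Channel -> region assignment with per-region coefficient sums."""

    region_of_channel: dict[str, int]
    region_sum: dict[int, float]

    def __post_init__(self):
        self.region_of_channel = {
            normalize_channel(k): int(v)
            for k, v in self.region_of_channel.items()
        }
        total = sum(self.region_sum.values())
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"region sums total {total!r}, expected 1.0")
        if any(v < 0 for v in self.region_sum.values()):
            raise ValidationError("region sums must be nonnegative")
        missing = set(self.region_of_channel.values()) - set(self.region_sum)
        if missing:
            raise ValidationError(f"regions {sorted(missing)} lack a sum")

    @property
    def channels(self) -> list[str]:
        return list(self.region_of_channel)

    def region(self, channel: str) -> int:
        key = normalize_channel(channel)
        if key not in self.region_of_channel:
            raise ValidationError(f"unknown channel {channel!r}")
        return self.region_of_channel[key]


@dataclass
class DatasetBundle:
    """Aligned trials, labels and subject ids."""

    recordings: list[MultichannelRecording]
    labels: np.ndarray
    subjects: np.ndarray
    label_scheme: str = "seed2"

    _SCHEMES = {
        "seed2": (0, 1),
        "seed3": (0, 1, 2),
        "deap_valence": (0, 1),
        "deap_arousal": (0, 1),
    }

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.subjects = np.asarray(self.subjects, dtype=int)
        n = len(self.recordings)
        if not (len(self.labels) == len(self.subjects) == n):
            raise ValidationError("recordings/labels/subjects length mismatch")
        if self.label_scheme not in self._SCHEMES:
            raise ValidationError(f"unknown label scheme {self.label_scheme!r}")
        allowed = set(self._SCHEMES[self.label_scheme])
        if n and not set(self.labels.tolist()) <= allowed:
            raise ValidationError(
                f"labels outside {sorted(allowed)} for {self.label_scheme}"
            )

    def __len__(self) -> int:
        return len(self.recordings)


# ---------------------------------------------------------------------------
# Montage presets
# ---------------------------------------------------------------------------

# Printed montage tables contain several non-standard labels; they are
# normalized here and the mapping is documented:
#   EP1 -> FP1, AP4 -> AF4, 01 -> O1, FC8 -> FT8, and the duplicated
#   FC5 in SEED region 1 -> FC1 (the only 62-channel label otherwise absent).
# CB1/CB2, C8 and FC8/FT8 follow the printed lists; they are SEED cap labels
# rather than 10-20 standard names.
SEED_REGIONS: dict[int, list[str]] = {
    1: ["FP1", "AF3", "F7", "F5", "F3", "F1", "FT7", "FC5", "FC3", "FC1",
        "T7", "C5", "C3", "C1"],
    2: ["FP2", "AF4", "F2", "F4", "F6", "F8", "FC2", "FC4", "FC6", "FT8",
        "FPZ", "FZ", "FCZ", "CZ"],
    3: ["TP7", "CP5", "CP3", "CP1", "P7", "P5", "P3", "P1", "PO7", "PO5",
        "PO3", "CB1", "O1", "CPZ", "PZ", "POZ", "OZ"],
    4: ["CP2", "CP4", "CP6", "TP8", "P2", "P4", "P6", "P8", "PO4", "PO6",
        "PO8", "CB2", "O2", "C2", "C4", "C6", "C8"],
}

DEAP_REGIONS: dict[int, list[str]] = {
    1: ["FP1", "AF3", "F7", "F3", "FC5", "FC1", "T7", "C3"],
    2: ["FP2", "AF4", "F4", "F8", "FC2", "FC6", "FZ", "CZ"],
    3: ["CP5", "CP1", "P7", "P3", "PO3", "O1", "PZ", "OZ"],
    4: ["CP2", "CP6", "P4", "P8", "PO4", "O2", "C4", "T8"],
}

REGION_SUMS = {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1}


def region_weighting_preset(dataset: str) -> RegionWeighting:
    """Built-in four-region montage weighting for ``seed`` or ``deap``."""
    tables = {"seed": SEED_REGIONS, "deap": DEAP_REGIONS}
    if dataset not in tables:
        raise ValidationError(f"unknown dataset preset {dataset!r}")
    mapping: dict[str, int] = {}
    for region, channels in tables[dataset].items():
        for ch in channels:
            mapping.setdefault(normalize_channel(ch), region)
    return RegionWeighting(mapping, dict(REGION_SUMS))


def load_region_weighting(config=None, dataset: Optional[str] = None) -> RegionWeighting:
    """Load a region weighting from a config file or a named preset.

    The config format is key-value text: one ``channel = region`` line per
    channel and one ``region_sum_<id> = <value>`` line per region.  Blank
    lines and ``#`` comments are ignored.
    """
    if config is None:
        if dataset is None:
            raise ValidationError("need a config path or a dataset preset")
        return region_weighting_preset(dataset)
    mapping: dict[str, int] = {}
    sums: dict[int, float] = {}
    with open(config) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(
                    f"{config}:{lineno}: expected 'key = value'"
                )
            key, value = (part.strip() for part in line.split("=", 1))
            if key.lower().startswith("region_sum_"):
                sums[int(key[len("region_sum_"):])] = float(value)
            else:
                mapping[normalize_channel(key)] = int(value)
    if not mapping:
        raise ValidationError(f"{config}: no channel assignments found")
    return RegionWeighting(mapping, sums)


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------

def _infer_format(path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = str(path).rsplit(".", 1)[-1].lower()
    return {"edf": "edf", "csv": "csv", "h5": "hdf5", "hdf5": "hdf5"}.get(
        suffix, suffix
    )


def read_recording(path, format: Optional[str] = None,
                   fs: Optional[float] = None) -> MultichannelRecording:
    """Read a recording from EDF, CSV or HDF5.

    ``fs`` is taken from the file header for EDF/HDF5 and is required for
    CSV (which has nowhere to store it).
    """
    fmt = _infer_format(path, format)
    if fmt == "edf":
        data, file_fs, names = _edf.read_edf(path)
        return MultichannelRecording(data, fs or file_fs, names)
    if fmt == "csv":
        if fs is None:
            raise ValidationError("fs is required when reading CSV recordings")
        frame = pd.read_csv(path)
        return MultichannelRecording(
            frame.to_numpy(dtype=float).T, fs, [str(c) for c in frame.columns]
        )
    if fmt == "hdf5":
        with h5py.File(path, "r") as fh:
            data = fh["data"][()]
            names = [
                n.decode() if isinstance(n, bytes) else str(n)
                for n in fh["channel_names"][()]
            ]
            file_fs = float(fh.attrs["fs"])
        return MultichannelRecording(data, fs or file_fs, names)
    raise ValidationError(f"unknown recording format {fmt!r}")


def write_recording(rec: MultichannelRecording, path,
                    format: Optional[str] = None) -> None:
    fmt = _infer_format(path, format)
    if fmt == "edf":
        _edf.write_edf(path, rec.data, rec.fs, rec.channel_names)
    elif fmt == "csv":
        pd.DataFrame(rec.data.T, columns=rec.channel_names).to_csv(
            path, index=False, float_format="%.17g"
        )
    elif fmt == "hdf5":
        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=rec.data)
            fh.create_dataset(
                "channel_names",
                data=np.array(rec.channel_names, dtype=h5py.string_dtype()),
            )
            fh.attrs["fs"] = rec.fs
    else:
        raise ValidationError(f"unknown recording format {fmt!r}")


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def write_feature_table(tensor, path, format: Optional[str] = None) -> None:
    """Persist a FeatureTensor as CSV (long layout) or HDF5."""
    fmt = _infer_format(path, format)
    values = np.asarray(tensor.values, dtype=float)
    if values.size and not np.isfinite(values).all():
        raise ValidationError("feature tensor contains non-finite values")
    names = list(tensor.feature_names)
    if fmt == "csv":
        n_trials, n_windows = values.shape[:2]
        idx = pd.MultiIndex.from_product(
            [range(n_trials), range(n_windows)], names=["trial", "window"]
        )
        frame = pd.DataFrame(
            values.reshape(-1, len(names)) if values.size else
            np.empty((0, len(names))),
            index=idx, columns=names,
        )
        frame.to_csv(path, float_format="%.17g")
    elif fmt == "hdf5":
        with h5py.File(path, "w") as fh:
            fh.create_dataset("values", data=values)
            fh.create_dataset(
                "feature_names",
                data=np.array(names, dtype=h5py.string_dtype()),
            )
    else:
        raise ValidationError(f"unknown feature-table format {fmt!r}")


def read_feature_table(path, format: Optional[str] = None):
    """Read a feature table back as ``(values, feature_names)``."""
    fmt = _infer_format(path, format)
    if fmt == "csv":
        frame = pd.read_csv(path, index_col=["trial", "window"])
        names = [str(c) for c in frame.columns]
        if len(frame) == 0:
            return np.empty((0, 0, len(names))), names
        n_trials = frame.index.get_level_values("trial").nunique()
        n_windows = frame.index.get_level_values("window").nunique()
        values = frame.to_numpy(dtype=float).reshape(
            n_trials, n_windows, len(names)
        )
        return values, names
    if fmt == "hdf5":
        with h5py.File(path, "r") as fh:
            values = fh["values"][()]
            names = [
                n.decode() if isinstance(n, bytes) else str(n)
                for n in fh["feature_names"][()]
            ]
        return values, names
    raise ValidationError(f"unknown feature-table format {fmt!r}")
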