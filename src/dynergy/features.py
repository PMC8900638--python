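"""Windowed dynamic feature set for energy sequences.

Families
--------
* time domain (9): mean, population SD, first/second absolute differentials
  with SD-normalized variants, instability index (NSI), energy, Higuchi
  fractal dimension;
* frequency domain (25): Hjorth activity/mobility/complexity and AR-spectrum
  peak frequency / in-band power sum, each over theta/alpha/beta/gamma/all;
* dynamical (15): approximate entropy, db4 six-level wavelet entropies
  (per-component + total), differential entropy per band.

The default inventory has exactly 49 named entries.  The composition is a
reconstruction (the count is fixed, the enumeration is configurable); see the
README for the naming scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from statsmodels.regression.linear_model import burg as _burg

from . import _wavelet
from .energy import EnergySequence, WindowSpec, slide_windows
from .signal_io import ValidationError

__all__ = [
    "Band",
    "BANDS",
    "FeatureInventory",
    "FeatureTensor",
    "band_limit",
    "time_domain_features",
    "higuchi_fd",
    "nsi",
    "hjorth_band",
    "ar_spectrum_features",
    "approximate_entropy",
    "wavelet_entropy",
    "differential_entropy",
    "extract_feature_set",
    "select_named_features",
    "SEED17",
    "DEAP19",
]

#: sentinel for log-of-zero differential entropy (flagged in metadata)
DE_SENTINEL = -745.0


@dataclass(frozen=True)
class Band:
    name: str
    lo: float
    hi: float

    def validate(self, fs: float) -> "Band":
        hi = min(self.hi, fs / 2)
        if not 0 <= self.lo < hi:
            raise ValidationError(
                f"band {self.name}: [{self.lo}, {self.hi}] Hz invalid at "
                f"fs={fs}"
            )
        return Band(self.name, self.lo, hi)


BANDS: dict[str, Band] = {
    "delta": Band("delta", 1.0, 4.0),
    "theta": Band("theta", 4.0, 7.0),
    "alpha": Band("alpha", 8.0, 13.0),
    "beta": Band("beta", 14.0, 30.0),
    "gamma": Band("gamma", 31.0, 50.0),
    "all": Band("all", 0.0, np.inf),
}

_HJORTH_BANDS = ("theta", "alpha", "beta", "gamma", "all")
_AR_BANDS = ("theta", "alpha", "beta", "gamma", "all")
_DE_BANDS = ("delta", "theta", "alpha", "beta", "gamma", "all")
_WE_NAMES = ("we_a6", "we_d1", "we_d2", "we_d3", "we_d4", "we_d5", "we_d6",
             "we_total")


def band_limit(x: np.ndarray, band: Band, fs: float) -> np.ndarray:
    """Band-limit by DFT masking: zero all bins outside [lo, hi] Hz."""
    band = band.validate(fs)
    if band.lo <= 0 and band.hi >= fs / 2:
        return np.asarray(x, dtype=float)
    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    mask = (freqs >= band.lo) & (freqs <= band.hi)
    return np.fft.irfft(spectrum * mask, n=len(x))


# ---------------------------------------------------------------------------
# Time domain
# ---------------------------------------------------------------------------

def nsi(x: np.ndarray, n_segments: int = 20) -> float:
    """Instability index: SD of the means of ``n_segments`` equal segments."""
    x = np.asarray(x, dtype=float)
    if len(x) < n_segments:
        raise ValidationError(
            f"NSI needs at least {n_segments} samples, got {len(x)}"
        )
    means = np.array([seg.mean() for seg in np.array_split(x, n_segments)])
    return float(means.std())


def higuchi_fd(x: np.ndarray, k_max: int = 8) -> float:
    """Higuchi fractal dimension via curve-length scaling over k = 1..k_max.

    For each interval k the normalized curve length is averaged over the k
    possible start offsets; the dimension is minus the log-log slope.
    Constant input has no curve length and returns 1.0.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValidationError("Higuchi FD needs at least 3 samples")
    ks, lengths = [], []
    for k in range(1, k_max + 1):
        lm = []
        for m in range(1, k + 1):  # 1-based start offset
            n_i = (n - m) // k
            if n_i < 1:
                continue
            idx = m - 1 + np.arange(n_i + 1) * k
            dist = np.abs(np.diff(x[idx])).sum()
            lm.append(dist * (n - 1) / (n_i * k * k))
        if lm:
            ks.append(k)
            lengths.append(np.mean(lm))
    lengths = np.asarray(lengths)
    if np.all(lengths <= 0):  # constant signal
        return 1.0
    good = lengths > 0
    if good.sum() < 2:
        return 1.0
    slope = np.polyfit(np.log(np.asarray(ks)[good]), np.log(lengths[good]), 1)[0]
    return float(-slope)


def time_domain_features(x: np.ndarray, n_segments: int = 20,
                         fd_k_max: int = 8) -> dict[str, float]:
    """The nine time-domain descriptors of a window."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValidationError("time-domain features need >= 2 samples")
    mean = float(x.mean())
    sd = float(x.std())  # population (1/N) form
    diff1 = float(np.abs(np.diff(x)).mean())
    diff2 = float(np.abs(x[2:] - x[:-2]).sum() / (n - 2)) if n > 2 else 0.0
    if sd > 0:
        diff1_norm, diff2_norm = diff1 / sd, diff2 / sd
    else:
        diff1_norm = diff2_norm = 0.0
    return {
        "mean": mean,
        "sd": sd,
        "diff1": diff1,
        "diff1_norm": diff1_norm,
        "diff2": diff2,
        "diff2_norm": diff2_norm,
        "nsi": nsi(x, n_segments) if n >= n_segments else 0.0,
        "energy": float(np.sum(np.abs(x) ** 2)),
        "fd": higuchi_fd(x, fd_k_max) if n >= 3 else 1.0,
    }


# ---------------------------------------------------------------------------
# Frequency domain
# ---------------------------------------------------------------------------

def _mobility(y: np.ndarray, fs: float) -> float:
    vy = y.var()
    if vy <= 0:
        return 0.0
    dy = np.diff(y) * fs
    return float(np.sqrt(dy.var() / vy))


def hjorth_band(x: np.ndarray, band: Band, fs: float,
                mode: str = "mask") -> tuple[float, float, float]:
    """Hjorth (activity, mobility, complexity) of the band-limited window.

    ``mode='mask'`` (default) band-limits by DFT masking and computes the
    classic time-domain Hjorth triplet; ``mode='spectral'`` applies the same
    formulas to the in-band DFT magnitude sequence.
    """
    if mode == "mask":
        y = band_limit(x, band, fs)
    elif mode == "spectral":
        band = band.validate(fs)
        spectrum = np.abs(np.fft.rfft(x))
        freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
        y = spectrum[(freqs >= band.lo) & (freqs <= band.hi)]
        if len(y) < 3:
            return 0.0, 0.0, 0.0
    else:
        raise ValidationError(f"unknown hjorth mode {mode!r}")
    activity = float(y.var())
    if activity <= 0:
        return 0.0, 0.0, 0.0
    dy = np.diff(y) * fs
    mob = _mobility(y, fs)
    mob_d = _mobility(dy, fs)
    complexity = mob_d / mob if mob > 0 else 0.0
    return activity, mob, complexity


def _ar_spectrum(x: np.ndarray, fs: float, order: int,
                 n_grid: int) -> tuple[np.ndarray, np.ndarray, bool]:
    """AR (Burg) power spectrum on a uniform [0, fs/2] grid.

    Returns (freqs, power, used_fallback).  Falls back to the periodogram
    when the fitted model is unstable.
    """
    x = np.asarray(x, dtype=float)
    if len(x) <= 2 * order:
        raise ValidationError(
            f"AR({order}) needs more than {2 * order} samples"
        )
    freqs = np.linspace(0.0, fs / 2, n_grid)
    centered = x - x.mean()
    fallback = False
    try:
        rho, sigma2 = _burg(centered, order=order)
        a = -np.asarray(rho)  # x_t + sum a_k x_{t-k} = w_t
        # zeros of A(u) = 1 + sum a_k u^k must lie outside the unit circle
        roots = np.roots(np.concatenate([a[::-1], [1.0]]))
        if np.any(np.abs(roots) <= 1.0 + 1e-10):
            fallback = True
    except Exception:
        fallback = True
    if not fallback:
        omega = 2 * np.pi * freqs / fs
        response = 1.0 + np.exp(
            -1j * np.outer(omega, np.arange(1, order + 1))
        ) @ a.astype(complex)
        power = sigma2 / np.abs(response) ** 2
    else:
        from scipy.signal import periodogram

        nfft = 2 * (n_grid - 1)
        _, power = periodogram(centered, fs=fs, nfft=nfft, detrend=False)
        power = power[:n_grid] * fs / 2  # rescale density to plain power
    return freqs, power, fallback


def ar_spectrum_features(x: np.ndarray, fs: float, order: int = 10,
                         bands: Sequence[str] = _AR_BANDS,
                         n_grid: int = 512) -> dict[str, float]:
    """Per-band AR-spectrum peak frequency and in-band power sum."""
    freqs, power, _ = _ar_spectrum(x, fs, order, n_grid)
    out: dict[str, float] = {}
    for name in bands:
        band = BANDS[name].validate(fs)
        sel = (freqs >= band.lo) & (freqs <= band.hi)
        if not sel.any():
            out[f"ar_max_freq_{name}"] = 0.0
            out[f"ar_power_sum_{name}"] = 0.0
            continue
        sub = power[sel]
        out[f"ar_max_freq_{name}"] = float(freqs[sel][int(np.argmax(sub))])
        out[f"ar_power_sum_{name}"] = float(sub.sum())
    return out


# ---------------------------------------------------------------------------
# Dynamical features
# ---------------------------------------------------------------------------

def approximate_entropy(x: np.ndarray, m: int = 2,
                        r: Optional[float] = None) -> float:
    """Approximate entropy with Chebyshev distance and self-matches.

    ``r`` defaults to 0.2x the window's population SD; a strict ``< r``
    match criterion is used.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < m + 2:
        raise ValidationError(f"ApEn needs at least {m + 2} samples")
    if r is None:
        r = 0.2 * float(x.std())
    if not r > 0:
        raise ValidationError("ApEn tolerance r must be positive")

    def phi(dim: int) -> float:
        count = n - dim + 1
        emb = np.lib.stride_tricks.sliding_window_view(x, dim)
        dist = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=2)
        frac = (dist < r).sum(axis=1) / count
        return float(np.log(frac).mean())

    return phi(m) - phi(m + 1)


def wavelet_entropy(x: np.ndarray, levels: int = 6) -> dict[str, float]:
    """db4 multilevel Shannon entropies.

    Per component (A6, D1..D6): entropy of the normalized squared-coefficient
    distribution.  ``we_total``: entropy of the relative component energies.
    Natural logarithms throughout.
    """
    coeffs = _wavelet.wavedec(np.asarray(x, dtype=float), levels=levels)
    # wavedec order: [A6, D6, D5, D4, D3, D2, D1]
    components = {"we_a6": coeffs[0]}
    for j in range(1, levels + 1):
        components[f"we_d{j}"] = coeffs[levels + 1 - j]

    def shannon(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log(p)).sum()) if len(p) else 0.0

    out: dict[str, float] = {}
    energies = []
    for name, c in components.items():
        total = float((c ** 2).sum())
        energies.append(total)
        out[name] = shannon(c ** 2 / total) if total > 0 else 0.0
    energies = np.asarray(energies)
    grand = energies.sum()
    out["we_total"] = shannon(energies / grand) if grand > 0 else 0.0
    return out


def differential_entropy(x: np.ndarray, band: Band, fs: float) -> float:
    """Gaussian differential entropy of the band-limited window.

    ``0.5 * ln(2 pi e sigma^2)`` with sigma^2 the population variance of the
    DFT-masked band signal; natural log.  Zero variance returns a large
    negative sentinel.
    """
    y = band_limit(x, band, fs)
    var = float(y.var())
    if var <= 0:
        return DE_SENTINEL
    return float(0.5 * np.log(2 * np.pi * np.e * var))


# ---------------------------------------------------------------------------
# Inventory and extraction
# ---------------------------------------------------------------------------

def _default_names() -> list[str]:
    names = ["mean", "sd", "diff1", "diff1_norm", "diff2", "diff2_norm",
             "nsi", "energy", "fd"]
    for b in _HJORTH_BANDS:
        names += [f"hjorth_activity_{b}", f"hjorth_mobility_{b}",
                  f"hjorth_complexity_{b}"]
    for b in _AR_BANDS:
        names += [f"ar_max_freq_{b}", f"ar_power_sum_{b}"]
    names.append("apen")
    names += list(_WE_NAMES)
    names += [f"de_{b}" for b in _DE_BANDS]
    return names


@dataclass
class FeatureInventory:
    """Ordered, uniquely named feature list with extraction parameters."""

    names: list[str] = field(default_factory=_default_names)
    apen_m: int = 2
    apen_r_factor: float = 0.2
    ar_order: int = 10
    nsi_segments: int = 20
    fd_k_max: int = 8
    hjorth_mode: str = "mask"

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            dupes = {n for n in self.names if self.names.count(n) > 1}
            raise ValidationError(f"duplicate feature names: {sorted(dupes)}")
        if not self.names:
            raise ValidationError("inventory must be nonempty")

    def __len__(self) -> int:
        return len(self.names)

    def restrict(self, names: Iterable[str]) -> "FeatureInventory":
        names = list(names)
        known = set(self.names)
        unknown = [n for n in names if n not in known]
        if unknown:
            raise ValidationError(
                f"unknown feature names {unknown}; available: {self.names}"
            )
        return FeatureInventory(
            names, self.apen_m, self.apen_r_factor, self.ar_order,
            self.nsi_segments, self.fd_k_max, self.hjorth_mode,
        )


@dataclass
class FeatureTensor:
    """trials x windows x features with a named feature axis."""

    values: np.ndarray
    feature_names: list[str]
    window_spec: Optional[WindowSpec] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("feature tensor must be 3-D")
        if self.values.shape[2] != len(self.feature_names):
            raise ValidationError("feature axis does not match names")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[2]


def compute_window_features(x: np.ndarray, fs: float,
                            inventory: FeatureInventory) -> dict[str, float]:
    """Compute only the feature groups the inventory actually names."""
    wanted = set(inventory.names)
    values: dict[str, float] = {}

    time_names = {"mean", "sd", "diff1", "diff1_norm", "diff2", "diff2_norm",
                  "nsi", "energy", "fd"}
    if wanted & time_names:
        values.update(time_domain_features(
            x, inventory.nsi_segments, inventory.fd_k_max))
    for b in _HJORTH_BANDS:
        triplet = {f"hjorth_activity_{b}", f"hjorth_mobility_{b}",
                   f"hjorth_complexity_{b}"}
        if wanted & triplet:
            ac, mo, co = hjorth_band(x, BANDS[b], fs,
                                     mode=inventory.hjorth_mode)
            values[f"hjorth_activity_{b}"] = ac
            values[f"hjorth_mobility_{b}"] = mo
            values[f"hjorth_complexity_{b}"] = co
    ar_bands = [b for b in _AR_BANDS
                if {f"ar_max_freq_{b}", f"ar_power_sum_{b}"} & wanted]
    if ar_bands:
        values.update(ar_spectrum_features(
            x, fs, order=inventory.ar_order, bands=ar_bands))
    if "apen" in wanted:
        values["apen"] = approximate_entropy(
            x, m=inventory.apen_m,
            r=max(inventory.apen_r_factor * float(np.std(x)), 1e-12))
    if wanted & set(_WE_NAMES):
        values.update(wavelet_entropy(x))
    for b in _DE_BANDS:
        if f"de_{b}" in wanted:
            values[f"de_{b}"] = differential_entropy(x, BANDS[b], fs)
    return values


def extract_feature_set(es: EnergySequence, spec: WindowSpec = WindowSpec(),
                        inventory: Optional[FeatureInventory] = None
                        ) -> FeatureTensor:
    """One-trial feature tensor (1 x n_windows x n_features)."""
    inventory = inventory or FeatureInventory()
    windows = slide_windows(es, spec)
    rows = []
    flags: list[str] = []
    for k, w in enumerate(windows):
        vals = compute_window_features(w, es.fs, inventory)
        row = [vals[name] for name in inventory.names]
        for name, v in zip(inventory.names, row):
            if v == DE_SENTINEL:
                flags.append(f"window {k}: {name} had zero band variance")
        rows.append(row)
    return FeatureTensor(
        np.asarray(rows)[None, :, :], list(inventory.names), spec,
        meta={"fs": es.fs, "weighting": es.weighting, "flags": flags},
    )


def stack_feature_tensors(tensors: Sequence[FeatureTensor]) -> FeatureTensor:
    """Concatenate single-trial tensors along the trial axis."""
    if not tensors:
        raise ValidationError("nothing to stack")
    names = tensors[0].feature_names
    for t in tensors[1:]:
        if t.feature_names != names:
            raise ValidationError("inconsistent feature inventories")
    return FeatureTensor(
        np.concatenate([t.values for t in tensors], axis=0),
        list(names), tensors[0].window_spec,
        meta={"flags": sum((t.meta.get("flags", []) for t in tensors), [])},
    )


# Printed named subsets.  The time-domain Hjorth mobility/complexity entries
# coincide with the full-band frequency-domain ones (full-band DFT masking is
# the identity), so the 17-column layout repeats those two columns; the
# second occurrence is suffixed '#2' to keep output names unique.
SEED17: list[str] = [
    "diff1", "diff1_norm", "diff2", "diff2_norm", "nsi", "fd",
    "hjorth_mobility_all", "hjorth_complexity_all",
    "hjorth_mobility_beta", "hjorth_mobility_all",
    "hjorth_complexity_beta", "hjorth_complexity_all",
    "ar_max_freq_beta", "ar_max_freq_all",
    "de_gamma", "de_all", "we_total",
]

DEAP19: list[str] = SEED17 + ["we_d2", "ar_power_sum_all"]

_SUBSETS = {"seed17": SEED17, "deap19": DEAP19}


def select_named_features(t: FeatureTensor, subset) -> FeatureTensor:
    """Column-select a named subset ('seed17', 'deap19', or a name list)."""
    names = _SUBSETS.get(subset, subset) if isinstance(subset, str) else list(subset)
    if isinstance(names, str):
        raise ValidationError(
            f"unknown subset {subset!r}; available: {sorted(_SUBSETS)}"
        )
    index = {n: i for i, n in enumerate(t.feature_names)}
    unknown = [n for n in names if n not in index]
    if unknown:
        raise ValidationError(
            f"unknown feature names {unknown}; available: {t.feature_names}"
        )
    cols = [index[n] for n in names]
    out_names: list[str] = []
    seen: dict[str, int] = {}
    for n in names:
        seen[n] = seen.get(n, 0) + 1
        out_names.append(n if seen[n] == 1 else f"{n}#{seen[n]}")
    return FeatureTensor(
        t.values[:, :, cols], out_names, t.window_spec, dict(t.meta)
    )
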