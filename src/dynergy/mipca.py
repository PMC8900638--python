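"""Mutual-information + PCA feature reduction.

Pipeline: estimate a symmetric feature-by-feature mutual-information matrix,
eigendecompose it, rank components by contribution rate, and keep the leading
components up to a cumulative-contribution cutoff (default 0.95, intended
range 0.85-0.95).

MI is estimated with equal-width histograms, ``ceil(m ** (1/3))`` bins per
feature (the cube-root rule keeps the independence bias, roughly B^2/(2m),
negligible at the sample sizes this pipeline produces); the diagonal holds
each column's entropy under
the same binning.  ``literal=True`` replaces the diagonal with the
value-proportion entropy (each column min-shifted, normalized to sum 1, then
Shannon entropy over samples) for fidelity to the step-wise recipe, which is
otherwise ill-posed for negative-valued features and leaves the joint
distribution undefined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import h5py
import numpy as np

from .signal_io import ValidationError

__all__ = [
    "MIPCAModel",
    "value_proportions",
    "feature_entropy",
    "mutual_information_matrix",
    "fit_mipca",
    "transform",
    "save_model",
    "load_model",
]


def value_proportions(X: np.ndarray) -> np.ndarray:
    """Column-wise value proportions: min-shift to nonnegative, sum to 1.

    A column that is all zero after the shift (i.e. constant) gets uniform
    proportions.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need a 2-D matrix with at least 2 rows")
    shifted = X - np.minimum(X.min(axis=0), 0.0)
    totals = shifted.sum(axis=0)
    m = X.shape[0]
    out = np.empty_like(shifted)
    for j in range(X.shape[1]):
        if totals[j] > 0:
            out[:, j] = shifted[:, j] / totals[j]
        else:
            out[:, j] = 1.0 / m
    return out


def feature_entropy(p: np.ndarray) -> float:
    """Shannon entropy (natural log) of a proportion vector; 0 log 0 = 0."""
    p = np.asarray(p, dtype=float).ravel()
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValidationError("proportions must sum to 1")
    pos = p[p > 0]
    return float(-(pos * np.log(pos)).sum())


def _bin_indices(X: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bin index per entry, column-wise over each column's range."""
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    idx = np.floor((X - lo) / span * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def mutual_information_matrix(X: np.ndarray, n_bins: Optional[int] = None,
                              literal: bool = False) -> np.ndarray:
    """Histogram-estimated MI between every pair of feature columns.

    Diagonal entries are column entropies (MI of a column with itself) under
    the same binning, or value-proportion entropies when ``literal``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be 2-D")
    m, n = X.shape
    if n < 2:
        raise ValidationError("need at least 2 feature columns")
    if m < 2:
        raise ValidationError("need at least 2 samples")
    if n_bins is None:
        n_bins = int(np.ceil(m ** (1.0 / 3.0)))
    idx = _bin_indices(X, n_bins)
    marg = [np.bincount(idx[:, j], minlength=n_bins) for j in range(n)]
    h = [_entropy_from_counts(c) for c in marg]
    out = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1, n):
            joint = np.bincount(idx[:, j] * n_bins + idx[:, k],
                                minlength=n_bins * n_bins)
            h_joint = _entropy_from_counts(joint)
            out[j, k] = out[k, j] = max(h[j] + h[k] - h_joint, 0.0)
    if literal:
        P = value_proportions(X)
        for j in range(n):
            out[j, j] = feature_entropy(P[:, j])
    else:
        for j in range(n):
            out[j, j] = h[j]
    return out


@dataclass
class MIPCAModel:
    """Eigendecomposition of the MI matrix with a contribution cutoff."""

    mi_matrix: np.ndarray
    eigenvalues: np.ndarray          # descending
    eigenvectors: np.ndarray         # rows beta_k, aligned with eigenvalues
    contributions: np.ndarray        # sigma_k, sums to 1
    cumulative: np.ndarray           # delta_k, nondecreasing
    cutoff: float
    n_components: int                # l = smallest k with delta_k >= cutoff
    n_bins: int
    feature_names: Optional[list[str]] = None

    @property
    def decision_matrix(self) -> np.ndarray:
        """Top-l eigenvector rows (B_l)."""
        return self.eigenvectors[: self.n_components]


def fit_mipca(X: np.ndarray, cutoff: float = 0.95,
              n_bins: Optional[int] = None, literal: bool = False,
              feature_names: Optional[list[str]] = None) -> MIPCAModel:
    """Fit the MI-matrix eigendecomposition and pick the component count."""
    if not 0 < cutoff <= 1:
        raise ValidationError("cutoff must be in (0, 1]")
    mi = mutual_information_matrix(X, n_bins=n_bins, literal=literal)
    if not np.isfinite(mi).all():
        raise FloatingPointError("MI matrix contains non-finite values")
    return fit_mipca_from_matrix(
        mi, cutoff,
        n_bins=n_bins or int(np.ceil(np.asarray(X).shape[0] ** (1.0 / 3.0))),
        feature_names=feature_names,
    )


def fit_mipca_from_matrix(mi: np.ndarray, cutoff: float = 0.95,
                          n_bins: int = 0,
                          feature_names: Optional[list[str]] = None
                          ) -> MIPCAModel:
    """Eigendecompose a precomputed symmetric MI matrix."""
    mi = np.asarray(mi, dtype=float)
    if np.abs(mi - mi.T).max() > 1e-10:
        raise ValidationError("MI matrix must be symmetric")
    eigvals, eigvecs = np.linalg.eigh(mi)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    vectors = eigvecs[:, order].T  # rows = beta_k
    # sign convention: largest-magnitude entry of each row positive
    for k in range(vectors.shape[0]):
        pivot = np.argmax(np.abs(vectors[k]))
        if vectors[k, pivot] < 0:
            vectors[k] = -vectors[k]
    total = eigvals.sum()
    if total <= 0:
        raise ValidationError("MI matrix has nonpositive trace")
    contributions = eigvals / total
    cumulative = np.cumsum(contributions)
    n_components = int(np.searchsorted(cumulative, cutoff - 1e-12) + 1)
    n_components = min(n_components, len(eigvals))
    return MIPCAModel(mi, eigvals, vectors, contributions, cumulative,
                      cutoff, n_components, n_bins, feature_names)


def transform(model: MIPCAModel, X: np.ndarray) -> np.ndarray:
    """Project samples-by-features X onto the top-l components (Z = X B_l')."""
    X = np.asarray(X, dtype=float)
    n = model.eigenvectors.shape[1]
    if X.ndim != 2 or X.shape[1] != n:
        raise ValidationError(
            f"X must have {n} feature columns, got shape {X.shape}"
        )
    return X @ model.decision_matrix.T


def save_model(model: MIPCAModel, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("mi_matrix", data=model.mi_matrix)
        fh.create_dataset("eigenvalues", data=model.eigenvalues)
        fh.create_dataset("eigenvectors", data=model.eigenvectors)
        fh.attrs["cutoff"] = model.cutoff
        fh.attrs["n_bins"] = model.n_bins
        if model.feature_names:
            fh.create_dataset(
                "feature_names",
                data=np.array(model.feature_names, dtype=h5py.string_dtype()),
            )


def load_model(path) -> MIPCAModel:
    with h5py.File(path, "r") as fh:
        mi = fh["mi_matrix"][()]
        cutoff = float(fh.attrs["cutoff"])
        n_bins = int(fh.attrs["n_bins"])
        names = None
        if "feature_names" in fh:
            names = [
                n.decode() if isinstance(n, bytes) else str(n)
                for n in fh["feature_names"][()]
            ]
    return fit_mipca_from_matrix(mi, cutoff, n_bins, names)
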