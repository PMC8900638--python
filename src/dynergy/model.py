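"""Bi-LSTM window-sequence classifier and evaluation protocols.

The network stack is bidirectional LSTM (concatenated directions) ->
dropout -> LSTM (last state) -> dense -> softmax, trained with RMSprop on
categorical cross-entropy.  Two protocols are provided: leave-one-subject-out
and stratified trial-level 10-fold cross-validation, plus an RBF C-SVC
baseline over window-averaged per-trial feature vectors.

Feature standardization (z-score) is always fitted on the training fold only
and stored with the trained model for inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import accuracy_score, confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._nn import SequenceClassifier, cross_entropy, softmax
from .energy import WindowSpec, energy_sequence
from .features import (
    FeatureInventory,
    FeatureTensor,
    extract_feature_set,
    select_named_features,
    stack_feature_tensors,
)
from .mipca import fit_mipca, transform as mipca_transform
from .signal_io import DatasetBundle, RegionWeighting, ValidationError

__all__ = [
    "NetworkSpec",
    "EvaluationReport",
    "TrainedModel",
    "build_network",
    "train",
    "evaluate_loso",
    "evaluate_kfold",
    "baseline_svm",
    "extract_sequences",
]


@dataclass
class NetworkSpec:
    """Architecture and training hyperparameters."""

    input_size: int = 17
    seq_len: int = 29
    bilstm_units: int = 128
    dropout: float = 0.3
    lstm_units: int = 64
    dense1: int = 128
    n_classes: int = 2
    optimizer: str = "rmsprop"
    learning_rate: float = 0.001
    epochs: int = 46
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        sizes = (self.input_size, self.seq_len, self.bilstm_units,
                 self.lstm_units, self.dense1, self.batch_size)
        if any(s <= 0 for s in sizes):
            raise ValidationError("all layer sizes must be positive")
        if not 0 <= self.dropout < 1:
            raise ValidationError("dropout must be in [0, 1)")
        if self.n_classes < 2:
            raise ValidationError("need at least 2 classes")
        if self.optimizer.lower() != "rmsprop":
            raise ValidationError("only the rmsprop optimizer is supported")
        if self.epochs < 0:
            raise ValidationError("epochs must be nonnegative")


@dataclass
class EvaluationReport:
    protocol: str                 # {"loso", "kfold10", ...}
    unit_ids: list                # subject id or fold index per unit
    accuracies: list[float]
    mean_accuracy: float
    confusions: list[np.ndarray]
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(not 0 <= a <= 1 for a in self.accuracies):
            raise ValidationError("accuracies must lie in [0, 1]")
        expected = float(np.mean(self.accuracies)) if self.accuracies else 0.0
        if abs(self.mean_accuracy - expected) > 1e-9:
            raise ValidationError("mean accuracy inconsistent with units")


def build_network(spec: NetworkSpec) -> SequenceClassifier:
    """Untrained network; identical seeds give identical initial weights."""
    return SequenceClassifier(
        input_size=spec.input_size, n_classes=spec.n_classes,
        bilstm_units=spec.bilstm_units, dropout=spec.dropout,
        lstm_units=spec.lstm_units, dense_units=spec.dense1, seed=spec.seed,
    )


@dataclass
class TrainedModel:
    net: SequenceClassifier
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    loss_history: list[float]
    spec: NetworkSpec

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.feature_mean) / self.feature_sd

    def predict(self, sequences: np.ndarray) -> np.ndarray:
        return self.net.predict(self._standardize(sequences))

    def predict_proba(self, sequences: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(self._standardize(sequences))


def train(net: SequenceClassifier, sequences: np.ndarray, labels: np.ndarray,
          spec: NetworkSpec) -> TrainedModel:
    """RMSprop training on cross-entropy with per-feature z-scoring.

    Standardization statistics come from ``sequences`` (the training set)
    and travel with the returned model.
    """
    from ._nn import RMSProp

    x = np.asarray(sequences, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.ndim != 3:
        raise ValidationError("sequences must be trials x windows x features")
    if not np.isfinite(x).all():
        raise ValidationError("sequences contain non-finite values")
    if len(np.unique(y)) < 2:
        raise ValidationError("training labels contain a single class")
    if y.min() < 0 or y.max() >= spec.n_classes:
        raise ValidationError("labels out of range for spec.n_classes")

    mean = x.reshape(-1, x.shape[2]).mean(axis=0)
    sd = x.reshape(-1, x.shape[2]).std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    xs = (x - mean) / sd

    rng = np.random.default_rng(spec.seed)
    opt = RMSProp(lr=spec.learning_rate)
    history: list[float] = []
    n = len(xs)
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, spec.batch_size):
            sel = order[start: start + spec.batch_size]
            loss, grads = net.loss_and_grads(xs[sel], y[sel], train=True, rng=rng)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/Inf loss at epoch {epoch}, batch {start // spec.batch_size}"
                )
            opt.step(net.params, grads)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return TrainedModel(net, mean, sd, history, spec)


# ---------------------------------------------------------------------------
# Bundle -> window sequences
# ---------------------------------------------------------------------------

def extract_sequences(bundle: DatasetBundle,
                      weighting: Optional[RegionWeighting] = None,
                      window: WindowSpec = WindowSpec(),
                      inventory: Optional[FeatureInventory] = None,
                      subset=None) -> FeatureTensor:
    """Energy-project and feature-extract every trial of a bundle."""
    if inventory is None:
        inventory = FeatureInventory()
    if subset is not None:
        from .features import _SUBSETS
        names = _SUBSETS.get(subset, subset) if isinstance(subset, str) else subset
        inventory = inventory.restrict(sorted(set(names), key=names.index))
    tensors = []
    for rec in bundle.recordings:
        es = energy_sequence(rec, weighting)
        tensors.append(extract_feature_set(es, window, inventory))
    stacked = stack_feature_tensors(tensors)
    if subset is not None:
        stacked = select_named_features(stacked, subset)
    return stacked


def _fit_eval_fold(x: np.ndarray, y: np.ndarray, train_idx, test_idx,
                   spec: NetworkSpec, use_mipca: bool, mipca_cutoff: float,
                   fold_seed: int):
    x_train, x_test = x[train_idx], x[test_idx]
    if use_mipca:
        flat = x_train.reshape(-1, x_train.shape[2])
        model = fit_mipca(flat, cutoff=mipca_cutoff)
        x_train = mipca_transform(model, flat).reshape(
            len(train_idx), x.shape[1], -1)
        x_test = mipca_transform(
            model, x_test.reshape(-1, x.shape[2])
        ).reshape(len(test_idx), x.shape[1], -1)
    fold_spec = NetworkSpec(**{**asdict(spec),
                               "input_size": x_train.shape[2],
                               "seed": fold_seed})
    net = build_network(fold_spec)
    trained = train(net, x_train, y[train_idx], fold_spec)
    pred = trained.predict(x_test)
    acc = accuracy_score(y[test_idx], pred)
    conf = confusion_matrix(y[test_idx], pred,
                            labels=np.arange(spec.n_classes))
    return float(acc), conf


def evaluate_loso(bundle: DatasetBundle, spec: NetworkSpec,
                  sequences: Optional[np.ndarray] = None,
                  weighting: Optional[RegionWeighting] = None,
                  window: WindowSpec = WindowSpec(),
                  subset=None, use_mipca: bool = False,
                  mipca_cutoff: float = 0.95) -> EvaluationReport:
    """Leave-one-subject-out: one fold per subject, trained on the rest.

    ``sequences`` can carry precomputed trials x windows x features values
    (feature extraction is deterministic and label-free, so reusing it across
    folds leaks nothing); otherwise they are extracted from the bundle.
    """
    subjects = np.unique(bundle.subjects)
    if len(subjects) < 2:
        raise ValidationError("LOSO needs at least 2 subjects")
    if sequences is None:
        sequences = extract_sequences(bundle, weighting, window,
                                      subset=subset).values
    x = np.asarray(sequences, dtype=float)
    y = bundle.labels
    accs, confs, ids = [], [], []
    for k, subj in enumerate(subjects):
        test_idx = np.flatnonzero(bundle.subjects == subj)
        train_idx = np.flatnonzero(bundle.subjects != subj)
        acc, conf = _fit_eval_fold(x, y, train_idx, test_idx, spec,
                                   use_mipca, mipca_cutoff,
                                   fold_seed=spec.seed + k)
        accs.append(acc)
        confs.append(conf)
        ids.append(int(subj))
    return EvaluationReport("loso", ids, accs, float(np.mean(accs)), confs,
                            config={"spec": asdict(spec), "subset": str(subset)})


def evaluate_kfold(bundle: DatasetBundle, spec: NetworkSpec, k: int = 10,
                   seed: int = 0,
                   sequences: Optional[np.ndarray] = None,
                   weighting: Optional[RegionWeighting] = None,
                   window: WindowSpec = WindowSpec(),
                   subset=None, use_mipca: bool = False,
                   mipca_cutoff: float = 0.95) -> EvaluationReport:
    """Stratified trial-level k-fold cross-validation."""
    n = len(bundle)
    if k > n:
        raise ValidationError(f"k={k} exceeds {n} trials")
    if sequences is None:
        sequences = extract_sequences(bundle, weighting, window,
                                      subset=subset).values
    x = np.asarray(sequences, dtype=float)
    y = bundle.labels
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs, confs, ids = [], [], []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(x, y)):
        acc, conf = _fit_eval_fold(x, y, train_idx, test_idx, spec,
                                   use_mipca, mipca_cutoff,
                                   fold_seed=spec.seed + fold)
        accs.append(acc)
        confs.append(conf)
        ids.append(fold)
    return EvaluationReport(f"kfold{k}", ids, accs, float(np.mean(accs)),
                            confs,
                            config={"spec": asdict(spec), "seed": seed})


def svm_penalty_grid() -> np.ndarray:
    """Powers of two from 2^-3 to 2^8 inclusive (12 values)."""
    return 2.0 ** np.arange(-3, 9)


def baseline_svm(features: np.ndarray, labels: np.ndarray,
                 penalty_grid: Optional[Sequence[float]] = None,
                 outer_folds: int = 5, seed: int = 0) -> float:
    """RBF C-SVC baseline on window-averaged per-trial vectors.

    3-D trials x windows x features input is collapsed to per-trial vectors
    by averaging over windows.  The penalty C is selected by an inner 5-fold
    grid search; the returned number is the mean held-out accuracy over
    stratified outer folds.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 3:
        x = x.mean(axis=1)
    if x.ndim != 2:
        raise ValidationError("features must be 2-D or 3-D")
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValidationError("need at least 2 classes")
    sd = x.std(axis=0)
    if not np.isfinite(x).all() or np.all(sd == 0):
        raise ValidationError("degenerate feature matrix")
    grid = np.asarray(penalty_grid if penalty_grid is not None
                      else svm_penalty_grid(), dtype=float)
    clf = GridSearchCV(
        make_pipeline(StandardScaler(), SVC(kernel="rbf")),
        {"svc__C": grid}, cv=5, n_jobs=None,
    )
    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True,
                            random_state=seed)
    scores = cross_val_score(clf, x, y, cv=outer)
    return float(scores.mean())
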