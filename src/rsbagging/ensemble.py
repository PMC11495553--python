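"""Abstaining undersampling-bagging SVM ensemble for imbalanced cohorts.

The classifier (RSBagging) targets heavily imbalanced two-class clinical
datasets. The training set is resampled into N exactly balanced subsets —
every subset keeps the full minority class and draws an equally sized
random sample of the majority class — and a Gaussian-kernel SVM with
Platt-calibrated probabilities is fitted per subset. Prediction fuses the
N positive-class probabilities by soft voting with an abstention threshold
alpha in [0.5, 1]: a sample is labelled positive when the mean probability
p+ >= alpha, negative when 1 - p+ >= alpha, and left unclassified
otherwise. The Predict Rate metric reports the fraction of test samples
that received a decision; accuracy, sensitivity, specificity and F1 are
computed over decided samples only, with the minority class as positive.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.svm import SVC


@contextmanager
def _quiet_platt():
    # SVC(probability=True) IS the Platt calibration this model specifies;
    # silence sklearn's deprecation nudge toward CalibratedClassifierCV.
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*probability.*", category=FutureWarning
        )
        yield

from .eeg_io import doc_binary

__all__ = [
    "Dataset",
    "EnsembleConfig",
    "TrainedEnsemble",
    "PredictionResult",
    "EvaluationReport",
    "ABSTAIN",
    "TASKS",
    "stratified_split",
    "make_balanced_subsets",
    "train_ensemble",
    "predict",
    "evaluate",
    "fit_single_svm",
    "run_task",
    "build_task_dataset",
]

ABSTAIN = -1

TASKS = ("doc", "motor_LR", "motor_single_bilateral",
         "location_LR", "location_single_bilateral")


@dataclass
class Dataset:
    """Feature matrix with binary labels; positive (1) is the minority class."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise ValueError("X must be (n_samples, n_features) aligned with y")
        classes = set(np.unique(self.y))
        if not classes <= {0, 1}:
            raise ValueError("labels must be binary 0/1")

    @property
    def n_positive(self) -> int:
        return int(self.y.sum())

    @property
    def n_negative(self) -> int:
        return int(len(self.y) - self.y.sum())

    def ensure_positive_minority(self) -> "Dataset":
        """Flip labels if the positive class is not the minority."""
        if self.n_positive > self.n_negative:
            return Dataset(self.X, 1 - self.y)
        return self


@dataclass
class EnsembleConfig:
    """Tunable parameters of the ensemble.

    N: number of base SVMs (odd default avoids hard-vote ties).
    alpha: abstention threshold of the soft vote, in [0.5, 1].
    svm_C, svm_gamma: Gaussian-kernel SVM hyperparameters ("scale" gives
    1 / (n_features * Var[X])).
    test_fraction / repeats: evaluation protocol of `run_task`.
    with_replacement: draw majority samples within a subset with
    replacement instead of the default without-replacement subsets.
    """

    N: int = 11
    alpha: float = 0.5
    svm_C: float = 1.0
    svm_gamma: float | str = "scale"
    seed: int = 0
    test_fraction: float = 0.3
    repeats: int = 20
    with_replacement: bool = False

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0.5 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0.5, 1]")
        if self.svm_C <= 0:
            raise ValueError("svm_C must be positive")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class TrainedEnsemble:
    """N fitted, probability-calibrated SVMs plus the fusion rule."""

    base_models: list
    config: EnsembleConfig
    subset_indices: list[np.ndarray]
    feature_mean: np.ndarray
    feature_std: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.feature_mean) / self.feature_std


@dataclass
class PredictionResult:
    """Fused predictions: 1, 0 or ABSTAIN (-1), plus mean p+ per sample."""

    labels: np.ndarray
    p_positive: np.ndarray


@dataclass
class EvaluationReport:
    """Confusion counts over decided samples and the five headline metrics.

    Metrics are percentages: accuracy, sensitivity, specificity and F1 over
    decided samples; predict_rate = decided / all test samples x 100.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    n_test: int
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    predict_rate: float
    all_abstained: bool = False
    per_repeat: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "n_test": self.n_test, "accuracy": self.accuracy,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "f1": self.f1, "predict_rate": self.predict_rate,
            "all_abstained": self.all_abstained,
        }


# ---------------------------------------------------------------------------
# Splitting and resampling


def stratified_split(
    data: Dataset, test_fraction: float, seed: int
) -> tuple[Dataset, Dataset]:
    """Seeded stratified split preserving per-class proportions.

    Per class, the test count is the class size times ``test_fraction``
    rounded to nearest; the split is disjoint and exhaustive.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx: list[np.ndarray] = []
    train_idx: list[np.ndarray] = []
    for cls in np.unique(data.y):
        idx = np.flatnonzero(data.y == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 samples")
        n_test = int(round(len(idx) * test_fraction))
        n_test = min(max(n_test, 1), len(idx) - 1)
        perm = rng.permutation(idx)
        test_idx.append(perm[:n_test])
        train_idx.append(perm[n_test:])
    te = np.sort(np.concatenate(test_idx))
    tr = np.sort(np.concatenate(train_idx))
    return Dataset(data.X[tr], data.y[tr]), Dataset(data.X[te], data.y[te])


def make_balanced_subsets(
    train: Dataset, N: int, seed: int, with_replacement: bool = False
) -> list[np.ndarray]:
    """Index sets of N balanced subsets of the training data.

    Each subset contains every minority (positive) sample plus an equally
    sized random draw of majority samples — without replacement within a
    subset by default, independently across subsets.
    """
    minority = np.flatnonzero(train.y == 1)
    majority = np.flatnonzero(train.y == 0)
    if len(minority) < 2:
        raise ValueError("minority class needs at least 2 training samples")
    if len(minority) > len(majority):
        raise ValueError("positive class must be the minority; relabel upstream")
    rng = np.random.default_rng(seed)
    subsets = []
    for _ in range(N):
        maj = rng.choice(majority, size=len(minority), replace=with_replacement)
        subsets.append(np.sort(np.concatenate([minority, maj])))
    return subsets


# ---------------------------------------------------------------------------
# Training, fusion, evaluation


def train_ensemble(train: Dataset, cfg: EnsembleConfig) -> TrainedEnsemble:
    """Fit the N-subset SVM ensemble.

    Features are z-scored with training-set statistics only; each base SVM
    uses a Gaussian kernel with Platt-calibrated probabilities. Fully
    deterministic given ``cfg.seed``.
    """
    train = train.ensure_positive_minority()
    if train.n_positive == 0:
        raise ValueError("training set has no positive samples")
    mean = train.X.mean(axis=0)
    std = train.X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    Xz = (train.X - mean) / std
    subsets = make_balanced_subsets(train, cfg.N, cfg.seed, cfg.with_replacement)
    models = []
    for n, idx in enumerate(subsets):
        y_sub = train.y[idx]
        if len(np.unique(y_sub)) < 2:
            raise ValueError(f"subset {n} is degenerate (single class)")
        with _quiet_platt():
            svm = SVC(
                kernel="rbf", C=cfg.svm_C, gamma=cfg.svm_gamma,
                probability=True, random_state=cfg.seed + n,
            )
            svm.fit(Xz[idx], y_sub)
        models.append(svm)
    return TrainedEnsemble(models, cfg, subsets, mean, std)


def predict(ens: TrainedEnsemble, X: np.ndarray) -> PredictionResult:
    """Soft-vote fusion with abstention.

    p+ is the mean positive-class probability over base models. Predict 1
    if p+ >= alpha, 0 if 1 - p+ >= alpha, otherwise abstain. At
    alpha = 0.5 the tie p+ = 0.5 goes to the positive (minority) class, so
    binary predictions always resolve and the Predict Rate is 100%.
    """
    if not ens.base_models:
        raise ValueError("empty ensemble")
    Xz = ens.transform(X)
    probs = np.stack(
        [m.predict_proba(Xz)[:, list(m.classes_).index(1)]
         for m in ens.base_models]
    )
    p_pos = probs.mean(axis=0)
    alpha = ens.config.alpha
    labels = np.full(len(p_pos), ABSTAIN, dtype=int)
    labels[p_pos >= alpha] = 1
    labels[(1 - p_pos >= alpha) & (labels == ABSTAIN)] = 0
    return PredictionResult(labels, p_pos)


def evaluate(pred: PredictionResult, y_true: np.ndarray) -> EvaluationReport:
    """Confusion counts and the five metrics.

    Abstained samples are excluded from the confusion counts but retained
    in the Predict Rate denominator (all positive plus negative test
    samples). Percentages throughout.
    """
    y_true = np.asarray(y_true, dtype=int)
    if len(y_true) != len(pred.labels):
        raise ValueError("prediction and label lengths differ")
    decided = pred.labels != ABSTAIN
    yp = pred.labels[decided]
    yt = y_true[decided]
    tp = int(np.sum((yp == 1) & (yt == 1)))
    tn = int(np.sum((yp == 0) & (yt == 0)))
    fp = int(np.sum((yp == 1) & (yt == 0)))
    fn = int(np.sum((yp == 0) & (yt == 1)))
    n_dec = tp + tn + fp + fn
    n_test = len(y_true)

    def pct(num: float, den: float) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    return EvaluationReport(
        tp=tp, tn=tn, fp=fp, fn=fn, n_test=n_test,
        accuracy=pct(tp + tn, n_dec),
        sensitivity=pct(tp, tp + fn),
        specificity=pct(tn, tn + fp),
        f1=pct(2 * tp, 2 * tp + fp + fn),
        predict_rate=pct(n_dec, n_test),
        all_abstained=(n_dec == 0),
    )


def fit_single_svm(train: Dataset, cfg: EnsembleConfig):
    """Baseline: one Gaussian-kernel SVM on the full (imbalanced) training
    set, z-scored the same way. Returns (model, transform)."""
    mean = train.X.mean(axis=0)
    std = np.where(train.X.std(axis=0) > 0, train.X.std(axis=0), 1.0)
    with _quiet_platt():
        svm = SVC(kernel="rbf", C=cfg.svm_C, gamma=cfg.svm_gamma,
                  probability=True, random_state=cfg.seed)
        svm.fit((train.X - mean) / std, train.y)
    return svm, lambda X: (np.asarray(X, dtype=float) - mean) / std


# ---------------------------------------------------------------------------
# Task-level protocol


def build_task_dataset(
    features: pd.DataFrame, labels: pd.DataFrame, task: str
) -> Dataset:
    """Join features with clinical labels and binarize for one task.

    Tasks (positive = minority class):

    * ``doc`` — any non-awake consciousness state vs awake;
    * ``motor_LR`` / ``location_LR`` — left vs right side, subjects with a
      disorder of consciousness and bilateral/none sides excluded;
    * ``motor_single_bilateral`` / ``location_single_bilateral`` —
      bilateral vs single-sided, DoC subjects excluded.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    merged = labels.merge(features, on="subject_id", how="inner")
    feat_cols = [c for c in features.columns if c != "subject_id"]
    if task == "doc":
        y = merged["consciousness"].map(doc_binary).to_numpy()
    else:
        col = "motor_side" if task.startswith("motor") else "stroke_side"
        merged = merged[merged["consciousness"].map(doc_binary) == 0]
        if task.endswith("_LR"):
            merged = merged[merged[col].isin(["L", "R"])]
            side = merged[col].to_numpy()
            counts = pd.Series(side).value_counts()
            minority = counts.idxmin()
            y = (side == minority).astype(int)
        else:
            merged = merged[merged[col].isin(["B", "L", "R"])]
            y = (merged[col] == "B").to_numpy().astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError(f"task {task!r} has a class with no subjects")
    return Dataset(merged[feat_cols].to_numpy(), y).ensure_positive_minority()


def run_task(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    task: str,
    cfg: EnsembleConfig,
) -> EvaluationReport:
    """Repeated stratified evaluation of the ensemble on one clinical task.

    Each repeat draws a fresh stratified split with a derived seed, trains
    the ensemble and evaluates on the held-out set. The returned report
    aggregates confusion counts over repeats; ``per_repeat`` holds each
    repeat's metrics.
    """
    data = build_task_dataset(features, labels, task)
    reports = []
    for r in range(cfg.repeats):
        seed_r = (cfg.seed + 7919 * r) % (2**31)
        tr, te = stratified_split(data, cfg.test_fraction, seed_r)
        ens = train_ensemble(tr, replace(cfg, seed=seed_r))
        rep = evaluate(predict(ens, te.X), te.y)
        reports.append(rep)
    agg = EvaluationReport(
        tp=sum(r.tp for r in reports),
        tn=sum(r.tn for r in reports),
        fp=sum(r.fp for r in reports),
        fn=sum(r.fn for r in reports),
        n_test=sum(r.n_test for r in reports),
        accuracy=float(np.nanmean([r.accuracy for r in reports])),
        sensitivity=float(np.nanmean([r.sensitivity for r in reports])),
        specificity=float(np.nanmean([r.specificity for r in reports])),
        f1=float(np.nanmean([r.f1 for r in reports])),
        predict_rate=float(np.mean([r.predict_rate for r in reports])),
        all_abstained=all(r.all_abstained for r in reports),
        per_repeat=[r.to_dict() for r in reports],
    )
    return agg
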