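"""One-vs-rest SVM on the fused precomputed kernel, plus the CV driver.

Each localization label gets an independent C-SVM trained on the same
fused kernel (binary relevance).  Decision values f(x) = sum_i y_i
alpha_i K(x, x_i) + b are mapped to [0, 1] per label with a Platt-style
sigmoid fitted on the training decision values, because the ranking
measures need comparable real-valued scores.  The label-set decision
thresholds the calibrated scores at 0.5, with an argmax fallback so
every sample receives at least one label.

``cross_validate`` runs the full pipeline under seeded k-fold CV:
features are encoded once (deterministic per sequence), but bandwidths,
fusion weights beta, the SVMs and the calibrators are all fitted on the
training fold only — held-out samples never influence the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold
from sklearn.svm import SVC

from . import metrics as metrics_mod
from . import mkl
from .dataset_io import MultiLabelDataset
from .features import ENCODER_ORDER, feature_matrices

METHODS = ("hsic", "average")


@dataclass
class CVConfig:
    """Hyperparameters for the cross-validation driver.

    gamma: "dim" (1/encoder-dimension), "median" (median heuristic on the
    training fold), a float, or a per-encoder mapping.  method: "hsic"
    for HSIC-optimized fusion weights, "average" for the uniform-weight
    baseline.
    """

    n_folds: int = 10
    C: float = 1.0
    nu1: float = mkl.DEFAULT_NU1
    threshold: float = 0.5
    gamma: str | float | Mapping[str, float] = "dim"
    method: str = "hsic"
    seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if not (0 < self.threshold < 1):
            raise ValueError(f"threshold must lie in (0, 1), got {self.threshold}")


@dataclass
class TrainedModel:
    """Per-label SVMs and calibrators fitted on one fused training kernel."""

    svms: list
    calibrators: list
    label_names: list[str]
    C: float
    n_train: int
    beta: np.ndarray | None = None
    gammas: dict[str, float] | None = None
    train_ids: list[str] | None = None

    @property
    def n_labels(self) -> int:
        return len(self.svms)


def _fit_sigmoid(decision: np.ndarray, y: np.ndarray) -> LogisticRegression:
    # Platt-style sigmoid on the 1-D decision values; lightly regularized
    # so separable folds stay numerically stable.
    lr = LogisticRegression(C=1e4)
    lr.fit(decision.reshape(-1, 1), y)
    return lr


def train_ovr(
    K_star: np.ndarray,
    Y: np.ndarray,
    C: float = 1.0,
    label_names: Sequence[str] | None = None,
    **model_info,
) -> TrainedModel:
    """Fit one binary SVM per label column on a precomputed kernel.

    Every label's classifier sees the same fused kernel; positives are
    the samples carrying that label, negatives all others.  A column
    without both classes raises, naming the label — that signals a
    dataset-construction failure upstream.
    """
    K_star = np.asarray(K_star, dtype=float)
    Y = np.asarray(Y, dtype=int)
    if Y.ndim != 2:
        raise ValueError("Y must be a 2-D binary matrix")
    if K_star.shape != (Y.shape[0], Y.shape[0]):
        raise ValueError(
            f"kernel shape {K_star.shape} does not match {Y.shape[0]} samples"
        )
    names = list(label_names) if label_names is not None else [
        f"label{j}" for j in range(Y.shape[1])
    ]
    svms, calibrators = [], []
    for j, name in enumerate(names):
        y = Y[:, j]
        if y.min() == y.max():
            raise ValueError(
                f"label {name!r} has only one class in the training set; "
                "cannot fit a one-vs-rest classifier"
            )
        svc = SVC(C=C, kernel="precomputed")
        svc.fit(K_star, y)
        calibrators.append(_fit_sigmoid(svc.decision_function(K_star), y))
        svms.append(svc)
    return TrainedModel(
        svms=svms, calibrators=calibrators, label_names=names, C=C,
        n_train=Y.shape[0], **model_info,
    )


def predict_decision(model: TrainedModel, K_cross: np.ndarray) -> np.ndarray:
    """Raw per-label decision values for a test-by-train kernel."""
    K_cross = np.asarray(K_cross, dtype=float)
    if K_cross.ndim != 2 or K_cross.shape[1] != model.n_train:
        raise ValueError(
            f"cross kernel has {K_cross.shape} but model was trained on "
            f"{model.n_train} samples"
        )
    return np.column_stack([svc.decision_function(K_cross) for svc in model.svms])


def predict_scores(model: TrainedModel, K_cross: np.ndarray) -> np.ndarray:
    """Calibrated per-label probabilities in [0, 1]."""
    decision = predict_decision(model, K_cross)
    cols = []
    for j, lr in enumerate(model.calibrators):
        proba = lr.predict_proba(decision[:, j].reshape(-1, 1))
        cols.append(proba[:, list(lr.classes_).index(1)])
    return np.column_stack(cols)


def predict_labels(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold scores at >= threshold; argmax fallback guarantees every
    sample at least one label."""
    scores = np.asarray(scores, dtype=float)
    yhat = (scores >= threshold).astype(np.int8)
    empty = np.flatnonzero(yhat.sum(axis=1) == 0)
    yhat[empty, np.argmax(scores[empty], axis=1)] = 1
    return yhat


@dataclass
class CVResult:
    """Per-fold evaluation reports plus mean/std aggregates."""

    fold_reports: list[metrics_mod.EvaluationReport]
    aggregate: dict[str, tuple[float, float]]
    betas: list[np.ndarray] = field(default_factory=list)
    config: CVConfig | None = None

    def mean(self, metric: str) -> float:
        return self.aggregate[metric][0]

    def std(self, metric: str) -> float:
        return self.aggregate[metric][1]


def _aggregate(reports: Sequence[metrics_mod.EvaluationReport]) -> dict[str, tuple[float, float]]:
    out = {}
    for name in metrics_mod.METRIC_NAMES:
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        vals = vals[np.isfinite(vals)]
        out[name] = (
            (float(vals.mean()), float(vals.std())) if vals.size else (float("nan"), float("nan"))
        )
    return out


def cross_validate(
    dataset: MultiLabelDataset,
    config: CVConfig | None = None,
    feature_bank: Mapping[str, np.ndarray] | None = None,
) -> CVResult:
    """Seeded k-fold cross-validation of the full pipeline.

    Per fold: per-encoder RBF kernels on the training rows, fusion
    weights (HSIC-optimized or uniform), one-vs-rest SVMs with Platt
    calibration, then scores and the six measures on the held-out rows.
    A label column left single-class by the fold split is skipped for
    that fold with a warning, and metrics cover the remaining labels.

    ``feature_bank`` lets callers substitute precomputed per-encoder
    feature matrices (rows aligned with the dataset); by default they
    are encoded from the sequences.
    """
    config = config or CVConfig()
    if dataset.n_samples < config.n_folds:
        raise ValueError(
            f"need at least n_folds={config.n_folds} samples, got {dataset.n_samples}"
        )
    bank = dict(feature_bank) if feature_bank is not None else feature_matrices(dataset.sequences)
    names = [n for n in ENCODER_ORDER if n in bank] or list(bank)
    Y = np.asarray(dataset.labels, dtype=int)

    kf = KFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    reports, betas = [], []
    for train_idx, test_idx in kf.split(np.arange(dataset.n_samples)):
        train_bank = {n: bank[n][train_idx] for n in names}
        test_bank = {n: bank[n][test_idx] for n in names}
        gammas = mkl.resolve_gammas(train_bank, config.gamma)
        kernels = mkl.build_kernel_bank(train_bank, gammas)
        K_list = [kernels[n] for n in names]
        Y_train, Y_test = Y[train_idx], Y[test_idx]

        if config.method == "hsic":
            beta = mkl.solve_hsic_mkl(K_list, mkl.ideal_kernel(Y_train), nu1=config.nu1)
        else:
            beta = mkl.uniform_weights(len(K_list))
        betas.append(beta)

        usable = [
            j for j in range(Y.shape[1])
            if 0 < Y_train[:, j].sum() < len(train_idx)
        ]
        skipped = [dataset.label_names[j] for j in range(Y.shape[1]) if j not in usable]
        if skipped:
            warnings.warn(
                f"fold lost all positives or negatives for label(s) {skipped}; "
                "their classifiers are skipped for this fold",
                stacklevel=2,
            )
        model = train_ovr(
            mkl.combine_kernels(K_list, beta),
            Y_train[:, usable],
            C=config.C,
            label_names=[dataset.label_names[j] for j in usable],
            beta=beta,
            gammas=gammas,
        )
        K_cross = mkl.cross_kernel(train_bank, test_bank, gammas, beta)
        scores = predict_scores(model, K_cross)
        yhat = predict_labels(scores, config.threshold)
        reports.append(metrics_mod.evaluate(Y_test[:, usable], scores, yhat))
    return CVResult(
        fold_reports=reports, aggregate=_aggregate(reports), betas=betas, config=config
    )
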