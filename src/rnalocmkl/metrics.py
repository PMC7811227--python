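"""Six multi-label evaluation measures.

Given a binary truth matrix Y (n x L), real-valued per-label scores and a
binary prediction matrix, this module computes:

* Average Precision (AP)  — for each sample, the mean over its true
  labels y_q of the fraction of true labels ranked at or above y_q;
  larger is better, 1 iff every sample's positives occupy the top ranks.
* Coverage (Cov)          — worst rank of a true label minus 1; in
  [0, L-1], smaller is better.
* Ranking Loss (L_r)      — fraction of (positive, negative) label pairs
  with score(positive) <= score(negative); ties count as losses.
* One-error (E_one)       — fraction of samples whose top-ranked label is
  not a true label.
* Accuracy (Acc)          — Jaccard overlap |Yhat ∩ Y| / |Yhat ∪ Y|
  between predicted and true label sets, averaged over samples.
* Hamming Loss (L_h)      — size of the symmetric difference divided by
  the number of labels, averaged over samples.

Ranks are assigned by descending score with ties broken by ascending
label index.  Rows that do not satisfy a metric's denominator
assumptions (no positive label for the ranking measures; additionally no
negative label for ranking loss) are excluded from that metric's average
with a logged count; a metric with no qualifying rows is reported as NaN
rather than 0.  A sample with empty predicted and true label sets gets
accuracy 1 (perfect agreement on the empty set).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

logger = logging.getLogger(__name__)

LARGER_IS_BETTER = ("average_precision", "accuracy")
SMALLER_IS_BETTER = ("coverage", "ranking_loss", "hamming_loss", "one_error")
METRIC_NAMES = LARGER_IS_BETTER + SMALLER_IS_BETTER


@dataclass
class EvaluationReport:
    """Aggregate values of the six measures over one evaluation set."""

    average_precision: float
    accuracy: float
    coverage: float
    ranking_loss: float
    hamming_loss: float
    one_error: float
    n_samples: int

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def __str__(self) -> str:  # human-readable table
        rows = [f"  {name:<18} {getattr(self, name):.4f}" for name in METRIC_NAMES]
        return f"EvaluationReport (n={self.n_samples})\n" + "\n".join(rows)


def _validate(Y: np.ndarray, other: np.ndarray, what: str) -> tuple[np.ndarray, np.ndarray]:
    Y = np.asarray(Y)
    other = np.asarray(other)
    if Y.shape != other.shape or Y.ndim != 2:
        raise ValueError(f"{what} shape {other.shape} does not match labels {Y.shape}")
    if not np.isin(Y, (0, 1)).all():
        raise ValueError("label matrix must be binary")
    return Y.astype(int), other


def rank_labels(scores: np.ndarray) -> np.ndarray:
    """Per-sample ranks 1..L by descending score, ties by ascending index."""
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    order = np.argsort(-scores, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(scores.shape[0])[:, None]
    ranks[rows, order] = np.arange(1, scores.shape[1] + 1)
    return ranks


def ranking_metrics(Y: np.ndarray, scores: np.ndarray) -> dict[str, float]:
    """AP, coverage, ranking loss and one-error from real-valued scores."""
    Y, scores = _validate(Y, np.asarray(scores, dtype=float), "scores")
    ranks = rank_labels(scores)
    ap_terms, cov_terms, rl_terms, oe_terms = [], [], [], []
    for i in range(Y.shape[0]):
        pos = np.flatnonzero(Y[i] == 1)
        neg = np.flatnonzero(Y[i] == 0)
        if pos.size:
            r_pos = ranks[i, pos]
            ap_terms.append(
                np.mean([(r_pos <= r).sum() / r for r in r_pos])
            )
            cov_terms.append(r_pos.max() - 1)
            top = int(np.argmax(ranks[i] == 1))
            oe_terms.append(0.0 if Y[i, top] == 1 else 1.0)
        if pos.size and neg.size:
            bad = (scores[i, pos][:, None] <= scores[i, neg][None, :]).sum()
            rl_terms.append(bad / (pos.size * neg.size))
    n = Y.shape[0]
    skipped_rank = n - len(ap_terms)
    skipped_rl = n - len(rl_terms)
    if skipped_rank or skipped_rl:
        logger.info(
            "ranking metrics skipped %d row(s) without positives and %d without "
            "a positive/negative pair",
            skipped_rank,
            skipped_rl,
        )
    mean = lambda xs: float(np.mean(xs)) if xs else float("nan")
    return {
        "average_precision": mean(ap_terms),
        "coverage": mean(cov_terms),
        "ranking_loss": mean(rl_terms),
        "one_error": mean(oe_terms),
    }


def set_metrics(Y: np.ndarray, Yhat: np.ndarray) -> dict[str, float]:
    """Jaccard accuracy and Hamming loss from binary predictions."""
    Y, Yhat = _validate(Y, Yhat, "predictions")
    if not np.isin(Yhat, (0, 1)).all():
        raise ValueError("prediction matrix must be binary")
    Yhat = Yhat.astype(int)
    inter = (Y & Yhat).sum(axis=1)
    union = (Y | Yhat).sum(axis=1)
    acc = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    hamming = (Y ^ Yhat).sum(axis=1) / Y.shape[1]
    return {
        "accuracy": float(acc.mean()),
        "hamming_loss": float(hamming.mean()),
    }


def evaluate(Y: np.ndarray, scores: np.ndarray, Yhat: np.ndarray) -> EvaluationReport:
    """All six measures for one evaluation set."""
    vals: Mapping[str, float] = {**ranking_metrics(Y, scores), **set_metrics(Y, Yhat)}
    return EvaluationReport(n_samples=np.asarray(Y).shape[0], **vals)
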