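"""Ranking- and set-based multilabel evaluation measures.

Five measures are computed from a real-valued score matrix f(x_i, y), a
binary prediction matrix, and the true label matrix:

* **average precision** — mean over true labels of the fraction of labels
  ranked at or above them that are themselves true (1 is perfect);
* **coverage** — how far down the ranked label list one must go to reach
  every true label, reported both raw (0..Q−1) and divided by Q;
* **ranking loss** — fraction of (true, false) label pairs that are
  reversely ordered, f(true) ≤ f(false) (0 is perfect);
* **hamming loss** — fraction of misclassified instance–label pairs;
* **one-error** — fraction of instances whose single top-ranked label is
  not a true label.

Plus per-label accuracy (the per-syndrome recognition rates).

Ranks are deterministic: rank 1 is the highest score, score ties break
toward the lower label index.  Instances for which a ranking measure is
undefined (no true label; for ranking loss also no false label) are
skipped, with the denominator reduced and the skip count reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EvaluationInput",
    "MetricsReport",
    "ranks_from_scores",
    "average_precision",
    "coverage",
    "ranking_loss",
    "hamming_loss",
    "one_error",
    "per_label_accuracy",
    "evaluate",
]


@dataclass
class EvaluationInput:
    """Scores f(x_i, y), binary predictions, and true labels, all (p × Q)."""

    scores: np.ndarray
    predictions: np.ndarray
    truth: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.predictions = np.asarray(self.predictions)
        self.truth = np.asarray(self.truth)
        if not (self.scores.shape == self.predictions.shape == self.truth.shape):
            raise ValueError("scores, predictions and truth must share one shape")
        if self.scores.ndim != 2:
            raise ValueError("inputs must be 2-D (instances × labels)")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")
        for m, what in ((self.predictions, "predictions"), (self.truth, "truth")):
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"{what} must be binary")

    @property
    def n_instances(self) -> int:
        return self.scores.shape[0]

    @property
    def n_labels(self) -> int:
        return self.scores.shape[1]


@dataclass
class MetricsReport:
    average_precision: float
    coverage_raw: float
    coverage_normalized: float
    ranking_loss: float
    hamming_loss: float
    one_error: float
    per_label_accuracy: np.ndarray
    skipped_instances: int

    def to_dict(self) -> dict:
        return {
            "average_precision": self.average_precision,
            "coverage_raw": self.coverage_raw,
            "coverage_normalized": self.coverage_normalized,
            "ranking_loss": self.ranking_loss,
            "hamming_loss": self.hamming_loss,
            "one_error": self.one_error,
            "per_label_accuracy": [float(a) for a in self.per_label_accuracy],
            "skipped_instances": self.skipped_instances,
        }


def ranks_from_scores(score_row) -> np.ndarray:
    """Ranks 1..Q for one score row; rank 1 = highest, ties to lower index."""
    s = np.asarray(score_row, dtype=float).ravel()
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    order = np.argsort(-s, kind="stable")
    ranks = np.empty(s.size, dtype=np.int64)
    ranks[order] = np.arange(1, s.size + 1)
    return ranks


def _rank_matrix(scores: np.ndarray) -> np.ndarray:
    order = np.argsort(-scores, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(scores.shape[0])[:, None]
    ranks[rows, order] = np.arange(1, scores.shape[1] + 1)[None, :]
    return ranks


def average_precision(inp: EvaluationInput) -> float:
    """Mean precision at the rank of each true label; skips empty truth rows."""
    sizes = inp.truth.sum(axis=1)
    keep = np.flatnonzero(sizes >= 1)
    if keep.size == 0:
        raise ValueError("average precision undefined: every truth row is empty")
    ranks = _rank_matrix(inp.scores)
    total = 0.0
    for i in keep:
        true_ranks = ranks[i, inp.truth[i] == 1]
        inst = np.mean(
            [(true_ranks <= r).sum() / r for r in true_ranks]
        )
        total += inst
    return total / keep.size


def coverage(inp: EvaluationInput) -> tuple[float, float]:
    """(raw, raw / Q): mean depth-minus-one needed to cover all true labels."""
    sizes = inp.truth.sum(axis=1)
    keep = np.flatnonzero(sizes >= 1)
    if keep.size == 0:
        raise ValueError("coverage undefined: every truth row is empty")
    ranks = _rank_matrix(inp.scores)
    masked = np.where(inp.truth[keep] == 1, ranks[keep], 0)
    raw = float(np.mean(masked.max(axis=1) - 1))
    return raw, raw / inp.n_labels


def ranking_loss(inp: EvaluationInput) -> float:
    """Fraction of (true, false) label pairs with f(true) <= f(false)."""
    sizes = inp.truth.sum(axis=1)
    keep = np.flatnonzero((sizes >= 1) & (sizes <= inp.n_labels - 1))
    if keep.size == 0:
        raise ValueError(
            "ranking loss undefined: no instance has both true and false labels"
        )
    total = 0.0
    for i in keep:
        pos = inp.scores[i, inp.truth[i] == 1]
        neg = inp.scores[i, inp.truth[i] == 0]
        reversed_pairs = (pos[:, None] <= neg[None, :]).sum()
        total += reversed_pairs / (pos.size * neg.size)
    return total / keep.size


def hamming_loss(inp: EvaluationInput) -> float:
    """Fraction of instance-label pairs where prediction and truth disagree."""
    return float(np.mean(inp.predictions != inp.truth))


def one_error(inp: EvaluationInput) -> float:
    """Fraction of instances whose top-scored label is not a true label."""
    sizes = inp.truth.sum(axis=1)
    keep = np.flatnonzero(sizes >= 1)
    if keep.size == 0:
        raise ValueError("one-error undefined: every truth row is empty")
    top = np.argmax(inp.scores[keep], axis=1)  # lowest index on ties
    return float(np.mean(inp.truth[keep, top] == 0))


def per_label_accuracy(inp: EvaluationInput) -> np.ndarray:
    """Per-label fraction of instances with prediction bit equal to truth bit."""
    return np.mean(inp.predictions == inp.truth, axis=0)


def evaluate(inp: EvaluationInput) -> MetricsReport:
    """All measures in one report.

    ``skipped_instances`` counts instances excluded from at least one
    ranking measure (empty truth set, or full truth set for ranking loss).
    """
    sizes = inp.truth.sum(axis=1)
    skipped = int(np.sum((sizes == 0) | (sizes == inp.n_labels)))
    cov_raw, cov_norm = coverage(inp)
    return MetricsReport(
        average_precision=average_precision(inp),
        coverage_raw=cov_raw,
        coverage_normalized=cov_norm,
        ranking_loss=ranking_loss(inp),
        hamming_loss=hamming_loss(inp),
        one_error=one_error(inp),
        per_label_accuracy=per_label_accuracy(inp),
        skipped_instances=skipped,
    )
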