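"""ML-kNN: multilabel k-nearest-neighbour learning with Bayesian posteriors.

For each label the classifier keeps two ingredients estimated from the
training set:

* a smoothed prior P(H1) = (s + Σ y_i) / (2s + n) that the label is present;
* likelihood tables P(E_j | H1) and P(E_j | H0), where E_j is the event
  that exactly j of an instance's k nearest neighbours carry the label.
  The tables are estimated by counting leave-one-out neighbourhoods over
  the training instances, with Laplace-style smoothing of strength s.

At query time the k nearest training rows (Hamming distance on the binary
feature vectors, distance ties broken toward the lower training-row index)
give the observed neighbour count j for each label, and the posterior

    P(H1 | E_j) = P(H1) P(E_j|H1) / (P(H1) P(E_j|H1) + P(H0) P(E_j|H0))

is both the ranking score and, thresholded at 0.5, the MAP prediction.
Used standalone this is the vanilla baseline in a single shared feature
space; the REAL model reuses the same machinery per label subspace.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data import Dataset

__all__ = [
    "MLkNNConfig",
    "LabelPrior",
    "LabelLikelihoodTable",
    "MLkNNStats",
    "nearest_neighbors",
    "fit_prior",
    "fit_likelihoods",
    "posterior_score",
    "mlknn_fit",
    "mlknn_predict",
    "stats_to_json",
    "stats_from_json",
]


@dataclass(frozen=True)
class MLkNNConfig:
    """k: neighbour count; s: smoothing strength (s=1 is Laplace)."""

    k: int = 10
    s: float = 1.0
    metric: str = "hamming"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.s < 0:
            raise ValueError("s must be >= 0")
        if self.metric != "hamming":
            raise ValueError(f"unsupported metric {self.metric!r}")


@dataclass(frozen=True)
class LabelPrior:
    p_h1: float

    @property
    def p_h0(self) -> float:
        return 1.0 - self.p_h1


@dataclass
class LabelLikelihoodTable:
    like_h1: np.ndarray  # P(E_j | H1), j = 0..k
    like_h0: np.ndarray  # P(E_j | H0)

    def __post_init__(self) -> None:
        self.like_h1 = np.asarray(self.like_h1, dtype=float)
        self.like_h0 = np.asarray(self.like_h0, dtype=float)
        for v in (self.like_h1, self.like_h0):
            if abs(v.sum() - 1.0) > 1e-12:
                raise ValueError("likelihood vector must sum to 1")


@dataclass
class MLkNNStats:
    """A fitted vanilla ML-kNN model (all labels share one feature space).

    ``train_features``/``train_labels`` are the reference set that neighbour
    queries run against; priors and likelihood tables are per label.
    """

    config: MLkNNConfig
    train_features: np.ndarray
    train_labels: np.ndarray
    priors: list[LabelPrior]
    likelihoods: list[LabelLikelihoodTable]
    label_names: list[str] = field(default_factory=list)


def _hamming_distances(reference: np.ndarray, queries: np.ndarray) -> np.ndarray:
    """(n_query, n_reference) exact Hamming distances between binary matrices.

    Computed as |x| + |y| − 2 x·y via one float64 matmul; all intermediate
    values are exact integers, so the result is exact.
    """
    R = reference.astype(np.float64)
    Q = queries.astype(np.float64)
    return Q.sum(axis=1)[:, None] + R.sum(axis=1)[None, :] - 2.0 * (Q @ R.T)


def _neighbor_indices(reference: np.ndarray, queries: np.ndarray, k: int,
                      loo: bool = False) -> np.ndarray:
    """k nearest reference rows per query; ties toward lower reference index.

    With ``loo=True`` (queries are the reference itself) each row is barred
    from its own neighbourhood.
    """
    D = _hamming_distances(reference, queries)
    if loo:
        np.fill_diagonal(D, reference.shape[1] + 1.0)
    order = np.argsort(D, axis=1, kind="stable")
    return order[:, :k]


def nearest_neighbors(reference, query, k: int,
                      exclude_index: int | None = None) -> list[int]:
    """Indices of the k reference rows nearest to one query vector."""
    reference = np.asarray(reference)
    query = np.asarray(query).reshape(1, -1)
    available = reference.shape[0] - (exclude_index is not None)
    if k > available:
        raise ValueError(f"k={k} exceeds the {available} available reference rows")
    D = _hamming_distances(reference, query)[0]
    if exclude_index is not None:
        D[exclude_index] = reference.shape[1] + 1.0
    order = np.argsort(D, kind="stable")
    return [int(i) for i in order[:k]]


def fit_prior(label_column, s: float) -> LabelPrior:
    """Smoothed prevalence prior: (s + Σy) / (2s + n)."""
    y = np.asarray(label_column).ravel()
    if y.size < 1:
        raise ValueError("label column must be non-empty")
    return LabelPrior(float((s + y.sum()) / (2.0 * s + y.size)))


def _likelihoods_from_deltas(delta: np.ndarray, y: np.ndarray, k: int,
                             s: float) -> LabelLikelihoodTable:
    c1 = np.bincount(delta[y == 1], minlength=k + 1).astype(float)
    c0 = np.bincount(delta[y == 0], minlength=k + 1).astype(float)
    like_h1 = (s + c1) / (s * (k + 1) + c1.sum())
    like_h0 = (s + c0) / (s * (k + 1) + c0.sum())
    return LabelLikelihoodTable(like_h1, like_h0)


def fit_likelihoods(features, label_column, config: MLkNNConfig) -> LabelLikelihoodTable:
    """Neighbour-count likelihood tables from leave-one-out neighbourhoods."""
    features = np.asarray(features)
    y = np.asarray(label_column).ravel()
    if features.shape[0] <= config.k:
        raise ValueError(
            f"need more than k={config.k} training instances, got {features.shape[0]}"
        )
    nbrs = _neighbor_indices(features, features, config.k, loo=True)
    delta = y[nbrs].sum(axis=1)
    return _likelihoods_from_deltas(delta, y, config.k, config.s)


def posterior_score(prior: LabelPrior, table: LabelLikelihoodTable,
                    observed_count: int) -> float:
    """P(H1 | E_j) for the observed neighbour count j."""
    j = int(observed_count)
    if not 0 <= j < table.like_h1.size:
        raise ValueError(f"observed count {j} outside 0..{table.like_h1.size - 1}")
    num = prior.p_h1 * table.like_h1[j]
    den = num + prior.p_h0 * table.like_h0[j]
    if den == 0:
        raise ZeroDivisionError(
            "posterior undefined: both hypotheses have zero mass; use s > 0"
        )
    return float(num / den)


def mlknn_fit(dataset: Dataset, config: MLkNNConfig = MLkNNConfig()) -> MLkNNStats:
    """Fit priors and likelihood tables for every label in the shared space."""
    X, Y = dataset.features, dataset.labels
    if X.shape[0] <= config.k:
        raise ValueError(
            f"need more than k={config.k} training instances, got {X.shape[0]}"
        )
    nbrs = _neighbor_indices(X, X, config.k, loo=True)
    priors, tables = [], []
    for l in range(dataset.n_labels):
        y = Y[:, l]
        priors.append(fit_prior(y, config.s))
        delta = y[nbrs].sum(axis=1)
        tables.append(_likelihoods_from_deltas(delta, y, config.k, config.s))
    return MLkNNStats(config, X.copy(), Y.copy(), priors, tables,
                      list(dataset.label_names))


def _posterior_columns(delta: np.ndarray, prior: LabelPrior,
                       table: LabelLikelihoodTable) -> np.ndarray:
    num = prior.p_h1 * table.like_h1[delta]
    den = num + prior.p_h0 * table.like_h0[delta]
    if np.any(den == 0):
        raise ZeroDivisionError(
            "posterior undefined: both hypotheses have zero mass; use s > 0"
        )
    return num / den


def mlknn_predict(stats: MLkNNStats, queries) -> tuple[np.ndarray, np.ndarray]:
    """MAP predictions and posterior scores for a batch of query rows.

    One shared neighbour set per query; per label, the neighbour count
    indexes that label's likelihood table.
    """
    queries = np.asarray(queries)
    if queries.ndim != 2 or queries.shape[1] != stats.train_features.shape[1]:
        raise ValueError(
            f"queries have {queries.shape[-1]} features, model expects "
            f"{stats.train_features.shape[1]}"
        )
    nbrs = _neighbor_indices(stats.train_features, queries, stats.config.k)
    Q = len(stats.priors)
    scores = np.empty((queries.shape[0], Q))
    for l in range(Q):
        delta = stats.train_labels[:, l][nbrs].sum(axis=1)
        scores[:, l] = _posterior_columns(delta, stats.priors[l],
                                          stats.likelihoods[l])
    return (scores > 0.5).astype(np.int8), scores


# --- JSON serialisation (bit-exact round-trip) -----------------------------

def stats_to_json(stats: MLkNNStats) -> str:
    payload = {
        "config": {"k": stats.config.k, "s": stats.config.s,
                   "metric": stats.config.metric},
        "train_features": stats.train_features.astype(int).tolist(),
        "train_labels": stats.train_labels.astype(int).tolist(),
        "priors": [p.p_h1 for p in stats.priors],
        "likelihoods": [
            {"like_h1": t.like_h1.tolist(), "like_h0": t.like_h0.tolist()}
            for t in stats.likelihoods
        ],
        "label_names": stats.label_names,
    }
    return json.dumps(payload)


def stats_from_json(text: str) -> MLkNNStats:
    payload = json.loads(text)
    cfg = MLkNNConfig(**payload["config"])
    return MLkNNStats(
        config=cfg,
        train_features=np.array(payload["train_features"], dtype=np.int8),
        train_labels=np.array(payload["train_labels"], dtype=np.int8),
        priors=[LabelPrior(p) for p in payload["priors"]],
        likelihoods=[
            LabelLikelihoodTable(np.array(t["like_h1"]), np.array(t["like_h0"]))
            for t in payload["likelihoods"]
        ],
        label_names=list(payload["label_names"]),
    )
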