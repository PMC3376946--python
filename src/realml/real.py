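"""REAL: per-label feature subspaces composed with ML-kNN posteriors.

Vanilla ML-kNN judges every label in the same shared feature space, so a
label whose evidence lives in a handful of symptoms is ranked by distances
dominated by symptoms that say nothing about it.  REAL ("relevant feature
for each label") gives each label its own geometry: a filter selector
picks the top-m features for that label, the training set is projected
onto that subspace, and the label's prior/likelihood tables — and at query
time its neighbour counts — are all computed there.  With m equal to the
full feature count the model degenerates exactly to vanilla ML-kNN.

Ranking scores across labels are the per-label posterior probabilities
taken as-is: although each is computed in a different subspace, posteriors
share the [0, 1] calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data import Dataset
from .feature_selection import METHODS, LabelSubspace, select_label_subspaces
from .metrics import ranks_from_scores  # noqa: F401  (rank rule lives with the metrics)
from .mlknn import (
    LabelLikelihoodTable,
    LabelPrior,
    MLkNNConfig,
    _likelihoods_from_deltas,
    _neighbor_indices,
    _posterior_columns,
    fit_prior,
)

__all__ = [
    "RealConfig",
    "RealModel",
    "real_fit",
    "real_predict",
    "ranks_from_scores",
    "model_to_json",
    "model_from_json",
]


@dataclass(frozen=True)
class RealConfig:
    """method: filter selector; num_features: m per label; knn: k and s."""

    method: str = "ig"
    num_features: int = 20
    knn: MLkNNConfig = field(default_factory=MLkNNConfig)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.num_features < 1:
            raise ValueError("num_features must be >= 1")


@dataclass
class _PerLabelStats:
    train_projection: np.ndarray  # training rows restricted to the subspace
    train_column: np.ndarray      # this label's training column
    prior: LabelPrior
    likelihoods: LabelLikelihoodTable


@dataclass
class RealModel:
    config: RealConfig
    subspaces: list[LabelSubspace]
    per_label_stats: list[_PerLabelStats]
    label_names: list[str]
    n_features: int  # width of the original (pre-projection) feature space


def real_fit(dataset: Dataset, config: RealConfig = RealConfig()) -> RealModel:
    """Select a subspace per label, then fit that label's tables inside it."""
    k, s = config.knn.k, config.knn.s
    if dataset.n_instances <= k:
        raise ValueError(
            f"need more than k={k} training instances, got {dataset.n_instances}"
        )
    subspaces = select_label_subspaces(dataset, config.method, config.num_features)
    stats: list[_PerLabelStats] = []
    for l, sub in enumerate(subspaces):
        y = dataset.labels[:, l]
        proj = dataset.features[:, sub.selected]
        nbrs = _neighbor_indices(proj, proj, k, loo=True)
        delta = y[nbrs].sum(axis=1)
        stats.append(
            _PerLabelStats(
                train_projection=proj.copy(),
                train_column=y.copy(),
                prior=fit_prior(y, s),
                likelihoods=_likelihoods_from_deltas(delta, y, k, s),
            )
        )
    return RealModel(config, subspaces, stats, list(dataset.label_names),
                     dataset.n_features)


def real_predict(model: RealModel, queries) -> tuple[np.ndarray, np.ndarray]:
    """Per label: project queries, find neighbours there, score the posterior."""
    queries = np.asarray(queries)
    if queries.ndim != 2 or queries.shape[1] != model.n_features:
        raise ValueError(
            f"queries have {queries.shape[-1]} features, model expects "
            f"{model.n_features}"
        )
    k = model.config.knn.k
    Q = len(model.subspaces)
    scores = np.empty((queries.shape[0], Q))
    for l, (sub, st) in enumerate(zip(model.subspaces, model.per_label_stats)):
        q_proj = queries[:, sub.selected]
        nbrs = _neighbor_indices(st.train_projection, q_proj, k)
        delta = st.train_column[nbrs].sum(axis=1)
        scores[:, l] = _posterior_columns(delta, st.prior, st.likelihoods)
    return (scores > 0.5).astype(np.int8), scores


# --- JSON serialisation ----------------------------------------------------

def model_to_json(model: RealModel, feature_names: list[str] | None = None) -> str:
    payload = {
        "config": {
            "method": model.config.method,
            "num_features": model.config.num_features,
            "knn": {"k": model.config.knn.k, "s": model.config.knn.s,
                    "metric": model.config.knn.metric},
        },
        "n_features": model.n_features,
        "label_names": model.label_names,
        "subspaces": [
            {
                "label_index": sub.label_index,
                "selected": sub.selected,
                "scores": sub.scores,
                "method": sub.method,
                "num_features": sub.num_features,
                "directions": sub.directions,
                "feature_names": (
                    [feature_names[j] for j in sub.selected]
                    if feature_names else None
                ),
            }
            for sub in model.subspaces
        ],
        "per_label_stats": [
            {
                "train_projection": st.train_projection.astype(int).tolist(),
                "train_column": st.train_column.astype(int).tolist(),
                "prior": st.prior.p_h1,
                "like_h1": st.likelihoods.like_h1.tolist(),
                "like_h0": st.likelihoods.like_h0.tolist(),
            }
            for st in model.per_label_stats
        ],
    }
    return json.dumps(payload)


def model_from_json(text: str) -> RealModel:
    payload = json.loads(text)
    cfg = payload["config"]
    config = RealConfig(
        method=cfg["method"],
        num_features=cfg["num_features"],
        knn=MLkNNConfig(**cfg["knn"]),
    )
    subspaces = [
        LabelSubspace(
            label_index=s["label_index"],
            selected=list(s["selected"]),
            scores=list(s["scores"]),
            method=s["method"],
            num_features=s["num_features"],
            directions=list(s["directions"]),
        )
        for s in payload["subspaces"]
    ]
    stats = [
        _PerLabelStats(
            train_projection=np.array(st["train_projection"], dtype=np.int8),
            train_column=np.array(st["train_column"], dtype=np.int8),
            prior=LabelPrior(st["prior"]),
            likelihoods=LabelLikelihoodTable(
                np.array(st["like_h1"]), np.array(st["like_h0"])
            ),
        )
        for st in payload["per_label_stats"]
    ]
    return RealModel(config, subspaces, stats, list(payload["label_names"]),
                     payload["n_features"])
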