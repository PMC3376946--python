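"""Cross-validation harness, feature-count sweep and model comparison.

All randomness flows from a single experiment seed: the seed fixes the
fold assignment, and models are deterministic given the data, so a run is
fully reproducible from its configuration.  Feature selection is refit
inside every training fold — the held-out fold never influences which
symptoms a label's subspace contains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import Dataset, FoldSplit, split_folds
from .metrics import EvaluationInput, MetricsReport, evaluate
from .mlknn import MLkNNConfig, mlknn_fit, mlknn_predict
from .real import RealConfig, real_fit, real_predict

__all__ = [
    "ExperimentConfig",
    "CVReport",
    "DEFAULT_SWEEP",
    "cross_validate",
    "feature_sweep",
    "sweep_frame",
    "plot_sweep",
    "compare_models",
    "comparison_frames",
]

logger = logging.getLogger(__name__)

# feature counts swept when studying how subspace size affects accuracy
DEFAULT_SWEEP = [112, 100, 70, 60, 50, 40, 30, 20, 10, 5]

_METRIC_FIELDS = [
    "average_precision",
    "coverage_raw",
    "coverage_normalized",
    "ranking_loss",
    "hamming_loss",
    "one_error",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """model: 'real' or 'mlknn'; folds, seed and the m values to sweep."""

    model: str = "real"
    real_config: RealConfig = field(default_factory=RealConfig)
    knn_config: MLkNNConfig = field(default_factory=MLkNNConfig)
    n_folds: int = 10
    seed: int = 0
    sweep_values: tuple[int, ...] = tuple(DEFAULT_SWEEP)

    def __post_init__(self) -> None:
        if self.model not in {"real", "mlknn"}:
            raise ValueError("model must be 'real' or 'mlknn'")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if any(m < 1 for m in self.sweep_values):
            raise ValueError("sweep values must be >= 1")


@dataclass
class CVReport:
    """Mean ± std of every metric across folds, plus per-label accuracy."""

    metric_means: dict[str, float]
    metric_stds: dict[str, float]
    per_label_accuracy_mean: np.ndarray
    per_label_accuracy_std: np.ndarray
    label_names: list[str]
    n_folds: int
    seed: int
    fold_reports: list[MetricsReport] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = {
            name: f"{self.metric_means[name]:.3f} ± {self.metric_stds[name]:.3f}"
            for name in _METRIC_FIELDS
        }
        return pd.DataFrame({"mean ± std": rows})

    def to_dict(self) -> dict:
        return {
            "metric_means": self.metric_means,
            "metric_stds": self.metric_stds,
            "per_label_accuracy_mean": [float(a) for a in
                                        self.per_label_accuracy_mean],
            "per_label_accuracy_std": [float(a) for a in
                                       self.per_label_accuracy_std],
            "label_names": self.label_names,
            "n_folds": self.n_folds,
            "seed": self.seed,
        }


def _fit_predict(train: Dataset, test_features: np.ndarray,
                 config: ExperimentConfig) -> tuple[np.ndarray, np.ndarray]:
    if config.model == "real":
        model = real_fit(train, config.real_config)
        return real_predict(model, test_features)
    stats = mlknn_fit(train, config.knn_config)
    return mlknn_predict(stats, test_features)


def _subset(dataset: Dataset, idx: np.ndarray) -> Dataset:
    return Dataset(
        dataset.features[idx],
        dataset.labels[idx],
        list(dataset.feature_names),
        list(dataset.label_names),
    )


def cross_validate(dataset: Dataset, config: ExperimentConfig,
                   folds: FoldSplit | None = None) -> CVReport:
    """k-fold CV with per-fold refitting (selection included); mean ± std."""
    if folds is None:
        folds = split_folds(dataset.n_instances, config.n_folds, config.seed)
    k = (config.real_config.knn.k if config.model == "real"
         else config.knn_config.k)
    reports: list[MetricsReport] = []
    for f in range(folds.n_folds):
        tr_idx, te_idx = folds.train_indices(f), folds.test_indices(f)
        if tr_idx.size <= k:
            raise ValueError(
                f"fold {f}: training split of {tr_idx.size} instances cannot "
                f"support k={k} neighbours"
            )
        train = _subset(dataset, tr_idx)
        preds, scores = _fit_predict(train, dataset.features[te_idx], config)
        reports.append(
            evaluate(EvaluationInput(scores, preds, dataset.labels[te_idx]))
        )
    means = {
        name: float(np.mean([getattr(r, name) for r in reports]))
        for name in _METRIC_FIELDS
    }
    stds = {
        name: float(np.std([getattr(r, name) for r in reports], ddof=1))
        for name in _METRIC_FIELDS
    }
    acc = np.stack([r.per_label_accuracy for r in reports])
    return CVReport(
        metric_means=means,
        metric_stds=stds,
        per_label_accuracy_mean=acc.mean(axis=0),
        per_label_accuracy_std=acc.std(axis=0, ddof=1),
        label_names=list(dataset.label_names),
        n_folds=folds.n_folds,
        seed=config.seed,
        fold_reports=reports,
    )


def feature_sweep(dataset: Dataset, config: ExperimentConfig
                  ) -> list[tuple[int, CVReport]]:
    """Cross-validate the REAL model at every m in ``config.sweep_values``.

    Reports both ranking average precision and mean per-label accuracy for
    each m (the two readings of "average accuracy" on a feature-count
    sweep); folds are shared across m values for a paired comparison.
    """
    folds = split_folds(dataset.n_instances, config.n_folds, config.seed)
    out = []
    for m in config.sweep_values:
        cfg = replace(config, model="real",
                      real_config=replace(config.real_config, num_features=m))
        logger.info("sweep: m=%d", m)
        out.append((m, cross_validate(dataset, cfg, folds=folds)))
    return out


def sweep_frame(sweep: list[tuple[int, CVReport]]) -> pd.DataFrame:
    rows = []
    for m, rep in sweep:
        row = {"m": m}
        for name in _METRIC_FIELDS:
            row[name] = rep.metric_means[name]
            row[name + "_std"] = rep.metric_stds[name]
        row["mean_label_accuracy"] = float(rep.per_label_accuracy_mean.mean())
        rows.append(row)
    return pd.DataFrame(rows)


def plot_sweep(sweep: list[tuple[int, CVReport]], path: str) -> None:
    """Average precision and mean per-label accuracy against m."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = sweep_frame(sweep).sort_values("m")
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(df["m"], df["average_precision"], "o-", label="average precision")
    ax.plot(df["m"], df["mean_label_accuracy"], "s--",
            label="mean per-label accuracy")
    ax.set_xlabel("number of selected features per label (m)")
    ax.set_ylabel("score")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def compare_models(dataset: Dataset, configs: dict[str, ExperimentConfig]
                   ) -> dict[str, CVReport]:
    """CV every configuration on one shared fold split (paired comparison).

    All configurations must agree on ``n_folds`` and ``seed`` so the fold
    assignment is identical across models.
    """
    seeds = {c.seed for c in configs.values()}
    nf = {c.n_folds for c in configs.values()}
    if len(seeds) != 1 or len(nf) != 1:
        raise ValueError("all configs must share n_folds and seed")
    folds = split_folds(dataset.n_instances, nf.pop(), seeds.pop())
    return {
        name: cross_validate(dataset, cfg, folds=folds)
        for name, cfg in configs.items()
    }


def comparison_frames(reports: dict[str, CVReport]
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(metrics × models, labels × models) summary tables."""
    metric_tbl = pd.DataFrame({
        name: {
            m: f"{rep.metric_means[m]:.3f} ± {rep.metric_stds[m]:.3f}"
            for m in _METRIC_FIELDS
        }
        for name, rep in reports.items()
    })
    label_tbl = pd.DataFrame({
        name: {
            lbl: f"{mu:.3f} ± {sd:.3f}"
            for lbl, mu, sd in zip(rep.label_names,
                                   rep.per_label_accuracy_mean,
                                   rep.per_label_accuracy_std)
        }
        for name, rep in reports.items()
    })
    return metric_tbl, label_tbl
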