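"""Domain containers and plumbing shared by every other module.

A study is a pair of row-aligned binary matrices: an instance × feature
matrix of symptoms/signs (present/absent) and an instance × label matrix of
syndrome diagnoses.  Both travel together as a :class:`Dataset`.  Missing or
non-binary cells are rejected outright — the modelling assumes a fully
observed binary scale.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "FoldSplit",
    "DataFormatError",
    "AlignmentError",
    "load_dataset",
    "load_matrix",
    "save_matrix",
    "split_folds",
]


class DataFormatError(ValueError):
    """A cell is not a 0/1 value (or a header/name constraint is violated)."""


class AlignmentError(ValueError):
    """Feature and label matrices do not describe the same instances."""


def _as_binary(a, what: str) -> np.ndarray:
    arr = np.asarray(a)
    if arr.ndim != 2:
        raise DataFormatError(f"{what} must be a 2-D matrix, got ndim={arr.ndim}")
    if not np.isin(arr, (0, 1)).all():
        bad = np.argwhere(~np.isin(arr, (0, 1)))[0]
        raise DataFormatError(
            f"{what} contains a non-binary entry at row {bad[0]}, column {bad[1]}"
        )
    return arr.astype(np.int8)


@dataclass
class Dataset:
    """Row-aligned binary feature and label matrices with column names.

    Attributes
    ----------
    features : (n, d) int array with entries in {0, 1}
        Symptom/sign indicators, one instance per row.
    labels : (n, Q) int array with entries in {0, 1}
        Syndrome indicators for the same instances.
    feature_names, label_names : list of str
        Unique column names matching the matrix widths.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    label_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = _as_binary(self.features, "features")
        self.labels = _as_binary(self.labels, "labels")
        if self.features.shape[0] != self.labels.shape[0]:
            raise AlignmentError(
                f"features have {self.features.shape[0]} rows but labels have "
                f"{self.labels.shape[0]}; the matrices must be row-aligned"
            )
        if self.features.shape[0] < 1:
            raise DataFormatError("dataset must contain at least one instance")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.features.shape[1])]
        if not self.label_names:
            self.label_names = [f"y{j}" for j in range(self.labels.shape[1])]
        for names, width, what in (
            (self.feature_names, self.features.shape[1], "feature_names"),
            (self.label_names, self.labels.shape[1], "label_names"),
        ):
            if len(names) != width:
                raise DataFormatError(
                    f"{what} has {len(names)} entries for {width} columns"
                )
            if len(set(names)) != len(names):
                raise DataFormatError(f"{what} contains duplicate names")

    @property
    def n_instances(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_labels(self) -> int:
        return self.labels.shape[1]


@dataclass
class FoldSplit:
    """Assignment of every instance to one of ``n_folds`` cross-validation folds."""

    fold_assignments: np.ndarray
    n_folds: int

    def __post_init__(self) -> None:
        self.fold_assignments = np.asarray(self.fold_assignments, dtype=np.int64)
        counts = np.bincount(self.fold_assignments, minlength=self.n_folds)
        if (counts == 0).any():
            raise ValueError("every fold must be non-empty")
        if counts.max() - counts.min() > 1:
            raise ValueError("fold sizes may differ by at most 1")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments != fold)


def _sep_for(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    return "\t" if ext in {".tsv", ".tab"} else ","


def load_matrix(path: str) -> tuple[np.ndarray, list[str]]:
    """Read one binary matrix CSV/TSV (header row mandatory, no index column)."""
    df = pd.read_csv(path, sep=_sep_for(path), header=0)
    names = [str(c) for c in df.columns]
    values = df.to_numpy()
    ok = np.isin(values, (0, 1)) if values.size else np.ones((0, len(names)), bool)
    if values.size and not ok.all():
        r, c = np.argwhere(~ok)[0]
        raise DataFormatError(
            f"{path}: non-binary value {values[r, c]!r} at row {r}, column {names[c]!r}"
        )
    return values.astype(np.int8, copy=False).reshape(len(df), len(names)), names


def load_dataset(features_path: str, labels_path: str) -> Dataset:
    """Load a row-aligned feature/label pair of CSV or TSV files.

    The delimiter is inferred from each file's extension (``.tsv``/``.tab``
    → tab, otherwise comma).  Row order is preserved.
    """
    X, feature_names = load_matrix(features_path)
    Y, label_names = load_matrix(labels_path)
    if X.shape[0] != Y.shape[0]:
        raise AlignmentError(
            f"{features_path} has {X.shape[0]} rows but {labels_path} has "
            f"{Y.shape[0]} rows"
        )
    return Dataset(X, Y, feature_names, label_names)


def save_matrix(matrix: np.ndarray, names: list[str], path: str) -> None:
    """Write a matrix as CSV/TSV with a header row; inverse of :func:`load_matrix`."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != len(names):
        raise DataFormatError(
            f"got {len(names)} column names for a matrix of shape {matrix.shape}"
        )
    pd.DataFrame(matrix, columns=names).to_csv(path, sep=_sep_for(path), index=False)


def split_folds(n_instances: int, n_folds: int, seed: int) -> FoldSplit:
    """Seeded balanced partition: random permutation, then round-robin.

    Deterministic for a fixed ``(n_instances, n_folds, seed)``; fold sizes
    differ by at most one.
    """
    if not 2 <= n_folds <= n_instances:
        raise ValueError(
            f"need 2 <= n_folds <= n_instances, got n_folds={n_folds}, "
            f"n_instances={n_instances}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_instances)
    assignments = np.empty(n_instances, dtype=np.int64)
    assignments[perm] = np.arange(n_instances) % n_folds
    return FoldSplit(assignments, n_folds)
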