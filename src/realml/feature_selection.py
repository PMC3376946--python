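"""Filter-style feature scoring and label-specific subset selection.

Each binary symptom is scored against one binary syndrome label with a
plug-in information measure, and the top-m features per label form that
label's private input subspace.  Four selectors are provided:

``mi`` / ``ig``
    Mutual information and information gain.  For discrete variables the
    two are the same quantity written two ways; both are kept because each
    is computed along its own algebraic route (joint/marginal ratio versus
    entropy difference), which doubles as an internal consistency check.
``cmim``
    Conditional-mutual-information maximisation: greedy, each new feature
    maximises the *minimum* information it adds beyond any already-selected
    feature, min_s I(X_c; Y | X_s).
``mrmr``
    Minimum-redundancy-maximum-relevance (MID form): each new feature
    maximises I(X_c; Y) − mean_s I(X_c; X_s).

All scores are in bits (log base 2), estimated with unsmoothed empirical
frequencies and the 0·log 0 := 0 convention.  Ties always break toward the
lower column index so selection is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import Dataset

__all__ = [
    "ContingencyTable2x2",
    "LabelSubspace",
    "crosstab",
    "mutual_information",
    "information_gain",
    "conditional_mutual_information",
    "rank_features",
    "cmim_select",
    "mrmr_select",
    "select_label_subspaces",
    "METHODS",
]

logger = logging.getLogger(__name__)

METHODS = ("mi", "ig", "cmim", "mrmr")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Joint counts of a binary feature x against a binary target y."""

    n11: int  # x=1, y=1
    n10: int  # x=1, y=0
    n01: int  # x=0, y=1
    n00: int  # x=0, y=0

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0 or self.n < 1:
            raise ValueError("contingency counts must be non-negative with n >= 1")


@dataclass
class LabelSubspace:
    """Ordered feature subset selected for a single label.

    ``selected`` and ``scores`` are parallel; ``directions`` holds the sign
    of the empirical association p(x=1|y=1) − p(x=1|y=0) for each selected
    feature (+1 positive evidence, −1 counter-evidence, 0 none), so that
    "specific" and "negative" symptoms can be told apart downstream.
    """

    label_index: int
    selected: list[int]
    scores: list[float]
    method: str
    num_features: int
    directions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected feature indices must be unique")
        if len(self.scores) != len(self.selected):
            raise ValueError("scores must parallel selected")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")


def _check_binary_vector(v, name: str) -> np.ndarray:
    v = np.asarray(v).ravel()
    if v.size < 1 or not np.isin(v, (0, 1)).all():
        raise ValueError(f"{name} must be a non-empty binary vector")
    return v.astype(np.int64)


def crosstab(x, y) -> ContingencyTable2x2:
    """Exact 2×2 joint counts of two equal-length binary vectors."""
    x = _check_binary_vector(x, "x")
    y = _check_binary_vector(y, "y")
    if x.size != y.size:
        raise ValueError(f"length mismatch: x has {x.size}, y has {y.size}")
    n11 = int(np.sum((x == 1) & (y == 1)))
    n10 = int(np.sum((x == 1) & (y == 0)))
    n01 = int(np.sum((x == 0) & (y == 1)))
    return ContingencyTable2x2(n11, n10, n01, x.size - n11 - n10 - n01)


def _xlog2x(p: np.ndarray) -> np.ndarray:
    # p * log2(p) with the 0 log 0 := 0 convention
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy (bits) of a probability vector."""
    return float(-_xlog2x(np.asarray(p, dtype=float)).sum())


def _mi_from_counts(n11, n10, n01, n00) -> np.ndarray:
    """Vectorised plug-in I(X;Y) in bits from 2×2 counts (arrays broadcast)."""
    n11, n10, n01, n00 = np.atleast_1d(
        *(np.asarray(a, dtype=float) for a in (n11, n10, n01, n00))
    )
    n = n11 + n10 + n01 + n00
    mi = np.zeros(np.broadcast(n11, n10, n01, n00).shape, dtype=float)
    px1 = (n11 + n10) / n
    py1 = (n11 + n01) / n
    for nxy, px, py in (
        (n11, px1, py1),
        (n10, px1, 1 - py1),
        (n01, 1 - px1, py1),
        (n00, 1 - px1, 1 - py1),
    ):
        pxy = nxy / n
        nz = pxy > 0
        term = np.zeros_like(mi)
        px_b, py_b = np.broadcast_to(px, mi.shape), np.broadcast_to(py, mi.shape)
        term[nz] = pxy[nz] * np.log2(pxy[nz] / (px_b[nz] * py_b[nz]))
        mi += term
    # clip the tiny negatives that cancellation can leave on independent tables
    return np.maximum(mi, 0.0)


def mutual_information(table: ContingencyTable2x2) -> float:
    """Plug-in mutual information of the table, in bits; in [0, 1] for binary X, Y."""
    return float(
        _mi_from_counts(table.n11, table.n10, table.n01, table.n00).item()
    )


def information_gain(table: ContingencyTable2x2) -> float:
    """IG = H(Y) − H(Y|X), plug-in entropies in bits.

    Algebraically identical to :func:`mutual_information` for discrete
    variables, but computed along the entropy-difference route.
    """
    n = float(table.n)
    ny1 = table.n11 + table.n01
    h_y = _entropy(np.array([ny1, n - ny1]) / n)
    h_y_given_x = 0.0
    for nx_y1, nx_y0 in ((table.n11, table.n10), (table.n01, table.n00)):
        nx = nx_y1 + nx_y0
        if nx > 0:
            h_y_given_x += (nx / n) * _entropy(np.array([nx_y1, nx_y0]) / nx)
    return max(h_y - h_y_given_x, 0.0)


def conditional_mutual_information(x, y, z) -> float:
    """I(X;Y|Z) = Σ_z p̂(z) I(X;Y|Z=z), bits; empty strata contribute 0."""
    x = _check_binary_vector(x, "x")
    y = _check_binary_vector(y, "y")
    z = _check_binary_vector(z, "z")
    if not (x.size == y.size == z.size):
        raise ValueError("x, y, z must have equal lengths")
    total = 0.0
    for zv in (0, 1):
        mask = z == zv
        nz = int(mask.sum())
        if nz == 0:
            continue
        total += (nz / x.size) * mutual_information(crosstab(x[mask], y[mask]))
    return total


def _column_counts(features: np.ndarray, y: np.ndarray):
    """2×2 counts of every feature column against y, via matrix products."""
    f = features.astype(np.float64)
    n11 = y.astype(np.float64) @ f
    col1 = f.sum(axis=0)
    n10 = col1 - n11
    n01 = y.sum() - n11
    n00 = features.shape[0] - n11 - n10 - n01
    return n11, n10, n01, n00


def _score_columns(features: np.ndarray, y: np.ndarray, method: str) -> np.ndarray:
    n11, n10, n01, n00 = _column_counts(features, y)
    if method == "mi":
        return _mi_from_counts(n11, n10, n01, n00)
    # entropy-difference route, vectorised
    n = float(features.shape[0])
    ny1 = float(y.sum())
    h_y = _entropy(np.array([ny1, n - ny1]) / n)
    h_cond = np.zeros(features.shape[1])
    for na, nb in ((n11, n10), (n01, n00)):
        nx = na + nb
        pos = nx > 0
        pa = np.zeros_like(na)
        pa[pos] = na[pos] / nx[pos]
        h = -(_xlog2x(pa) + _xlog2x(1 - pa))
        h_cond[pos] += (nx[pos] / n) * h[pos]
    return np.maximum(h_y - h_cond, 0.0)


def _directions(features: np.ndarray, y: np.ndarray, selected: list[int]) -> list[int]:
    y = np.asarray(y)
    pos, neg = y == 1, y == 0
    out = []
    for j in selected:
        p1 = features[pos, j].mean() if pos.any() else 0.0
        p0 = features[neg, j].mean() if neg.any() else 0.0
        out.append(int(np.sign(p1 - p0)))
    return out


# scores within this absolute tolerance (bits) are treated as tied, so the
# lower-index rule is not at the mercy of floating-point summation order
_TIE_TOL = 1e-12


def _argmax_lowest_index(objective: np.ndarray, available: np.ndarray) -> int:
    masked = np.where(available, objective, -np.inf)
    best = masked.max()
    return int(np.flatnonzero(masked >= best - _TIE_TOL)[0])


def _prep(features, y, m):
    features = np.asarray(features)
    y = _check_binary_vector(y, "y")
    if features.shape[0] != y.size:
        raise ValueError("features and y must have equal row counts")
    d = features.shape[1]
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > d:
        logger.warning("requested m=%d features but only d=%d exist; clipping", m, d)
        m = d
    return features.astype(np.int64), y, m


def rank_features(features, y, method: str = "ig", m: int = 20,
                  label_index: int = 0) -> LabelSubspace:
    """Univariate ranking: score every column, keep the top m.

    Ties break toward the lower column index; the returned score list is
    non-increasing.
    """
    if method not in {"mi", "ig"}:
        raise ValueError(f"rank_features supports mi/ig, got {method!r}")
    features, y, m = _prep(features, y, m)
    scores = _score_columns(features, y, method)
    order = np.argsort(-scores, kind="stable")[:m]
    return LabelSubspace(
        label_index=label_index,
        selected=[int(j) for j in order],
        scores=[float(scores[j]) for j in order],
        method=method,
        num_features=m,
        directions=_directions(features, y, list(order)),
    )


def cmim_select(features, y, m: int = 20, label_index: int = 0) -> LabelSubspace:
    """Greedy CMIM: first pick argmax MI, then argmax of min_s I(X_c;Y|X_s)."""
    features, y, m = _prep(features, y, m)
    d = features.shape[1]
    mi = _score_columns(features, y, "mi")
    selected: list[int] = []
    scores: list[float] = []
    # running minimum of I(Xc;Y|Xs) over already-selected s (first pick by MI)
    min_cmi = np.full(d, np.inf)
    available = np.ones(d, dtype=bool)
    for step in range(m):
        objective = mi if step == 0 else min_cmi
        pick = _argmax_lowest_index(objective, available)
        selected.append(pick)
        scores.append(float(objective[pick]))
        available[pick] = False
        if len(selected) == m:
            break
        # update each candidate's running min with conditioning on the new pick
        n_rows = features.shape[0]
        zmask = features[:, pick] == 1
        cmi = np.zeros(d)
        for part in (zmask, ~zmask):
            npart = int(part.sum())
            if npart == 0:
                continue
            n11, n10, n01, n00 = _column_counts(features[part], y[part])
            cmi += (npart / n_rows) * _mi_from_counts(n11, n10, n01, n00)
        min_cmi = np.minimum(min_cmi, cmi)
    return LabelSubspace(
        label_index=label_index,
        selected=selected,
        scores=scores,
        method="cmim",
        num_features=m,
        directions=_directions(features, y, selected),
    )


def mrmr_select(features, y, m: int = 20, label_index: int = 0) -> LabelSubspace:
    """Greedy mRMR (MID): maximise I(X_c;Y) − mean_s I(X_c;X_s)."""
    features, y, m = _prep(features, y, m)
    d = features.shape[1]
    relevance = _score_columns(features, y, "mi")
    selected: list[int] = []
    scores: list[float] = []
    redundancy_sum = np.zeros(d)
    available = np.ones(d, dtype=bool)
    for step in range(m):
        if step == 0:
            objective = relevance.copy()
        else:
            objective = relevance - redundancy_sum / step
        pick = _argmax_lowest_index(objective, available)
        selected.append(pick)
        scores.append(float(objective[pick]))
        available[pick] = False
        if len(selected) == m:
            break
        n11, n10, n01, n00 = _column_counts(features, features[:, pick])
        redundancy_sum += _mi_from_counts(n11, n10, n01, n00)
    return LabelSubspace(
        label_index=label_index,
        selected=selected,
        scores=scores,
        method="mrmr",
        num_features=m,
        directions=_directions(features, y, selected),
    )


def select_label_subspaces(dataset: Dataset, method: str = "ig",
                           m: int = 20) -> list[LabelSubspace]:
    """Apply the chosen selector independently to every label column.

    Subsets may overlap across labels — the same symptom can be evidence for
    several syndromes.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    out = []
    for l in range(dataset.n_labels):
        y = dataset.labels[:, l]
        if method in {"mi", "ig"}:
            sub = rank_features(dataset.features, y, method, m, label_index=l)
        elif method == "cmim":
            sub = cmim_select(dataset.features, y, m, label_index=l)
        else:
            sub = mrmr_select(dataset.features, y, m, label_index=l)
        out.append(sub)
    return out
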