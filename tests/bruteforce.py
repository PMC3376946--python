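"""Independent naive re-implementations used as oracles in tests.

Everything here is deliberately written with plain Python loops, sets and
``math.log2`` — no shared code with the package — so that agreement
between the two routes is meaningful.
"""

from __future__ import annotations

import math


# --- information measures --------------------------------------------------

def naive_mi(x, y) -> float:
    """Plug-in I(X;Y) in bits from two binary sequences, by cell loops."""
    n = len(x)
    mi = 0.0
    for xv in (0, 1):
        for yv in (0, 1):
            nxy = sum(1 for a, b in zip(x, y) if a == xv and b == yv)
            if nxy == 0:
                continue
            px = sum(1 for a in x if a == xv) / n
            py = sum(1 for b in y if b == yv) / n
            pxy = nxy / n
            mi += pxy * math.log2(pxy / (px * py))
    return max(mi, 0.0)


def naive_entropy(y) -> float:
    n = len(y)
    h = 0.0
    for v in (0, 1):
        p = sum(1 for a in y if a == v) / n
        if p > 0:
            h -= p * math.log2(p)
    return h


def naive_cmi(x, y, z) -> float:
    """I(X;Y|Z) by stratifying on z."""
    n = len(x)
    total = 0.0
    for zv in (0, 1):
        idx = [i for i in range(n) if z[i] == zv]
        if not idx:
            continue
        total += (len(idx) / n) * naive_mi([x[i] for i in idx],
                                           [y[i] for i in idx])
    return total


def naive_cmim(features, y, m) -> list[int]:
    """Greedy CMIM with explicit per-step evaluation of every candidate."""
    d = len(features[0])
    cols = [[row[j] for row in features] for j in range(d)]
    selected: list[int] = []
    for _ in range(min(m, d)):
        best_j, best_score = None, -math.inf
        for j in range(d):
            if j in selected:
                continue
            if not selected:
                score = naive_mi(cols[j], y)
            else:
                score = min(naive_cmi(cols[j], y, cols[s]) for s in selected)
            if score > best_score + 1e-12:  # near-ties keep the lower index
                best_j, best_score = j, score
        selected.append(best_j)
    return selected


def naive_mrmr(features, y, m) -> list[int]:
    """Greedy mRMR (MID) with explicit per-step evaluation."""
    d = len(features[0])
    cols = [[row[j] for row in features] for j in range(d)]
    selected: list[int] = []
    for _ in range(min(m, d)):
        best_j, best_score = None, -math.inf
        for j in range(d):
            if j in selected:
                continue
            rel = naive_mi(cols[j], y)
            if selected:
                red = sum(naive_mi(cols[j], cols[s]) for s in selected)
                score = rel - red / len(selected)
            else:
                score = rel
            if score > best_score + 1e-12:
                best_j, best_score = j, score
        selected.append(best_j)
    return selected


# --- multilabel metrics ----------------------------------------------------

def naive_ranks(scores) -> list[int]:
    """rank 1 = highest score; ties broken toward the lower label index."""
    Q = len(scores)
    return [
        1
        + sum(1 for j in range(Q) if scores[j] > scores[i])
        + sum(1 for j in range(i) if scores[j] == scores[i])
        for i in range(Q)
    ]


def _true_sets(truth):
    return [
        {j for j, t in enumerate(row) if t == 1}
        for row in truth
    ]


def naive_average_precision(scores, truth) -> float:
    vals = []
    for s_row, Y in zip(scores, _true_sets(truth)):
        if not Y:
            continue
        r = naive_ranks(s_row)
        vals.append(
            sum(sum(1 for yp in Y if r[yp] <= r[y]) / r[y] for y in Y) / len(Y)
        )
    return sum(vals) / len(vals)


def naive_coverage(scores, truth) -> float:
    vals = []
    for s_row, Y in zip(scores, _true_sets(truth)):
        if not Y:
            continue
        r = naive_ranks(s_row)
        vals.append(max(r[y] for y in Y) - 1)
    return sum(vals) / len(vals)


def naive_ranking_loss(scores, truth) -> float:
    Q = len(scores[0])
    vals = []
    for s_row, Y in zip(scores, _true_sets(truth)):
        Ybar = set(range(Q)) - Y
        if not Y or not Ybar:
            continue
        bad = sum(
            1 for y1 in Y for y2 in Ybar if s_row[y1] <= s_row[y2]
        )
        vals.append(bad / (len(Y) * len(Ybar)))
    return sum(vals) / len(vals)


def naive_hamming_loss(preds, truth) -> float:
    p = len(truth)
    Q = len(truth[0])
    total = 0
    for prow, trow in zip(preds, truth):
        P = {j for j, v in enumerate(prow) if v == 1}
        T = {j for j, v in enumerate(trow) if v == 1}
        total += len(P.symmetric_difference(T)) / Q
    return total / p


def naive_one_error(scores, truth) -> float:
    vals = []
    for s_row, Y in zip(scores, _true_sets(truth)):
        if not Y:
            continue
        top = max(range(len(s_row)), key=lambda j: (s_row[j], -j))
        vals.append(0 if top in Y else 1)
    return sum(vals) / len(vals)


# --- ML-kNN ----------------------------------------------------------------

def _ham(a, b) -> int:
    return sum(1 for u, v in zip(a, b) if u != v)


def naive_mlknn(Xtr, Ytr, Xte, k, s):
    """Full naive fit/predict: enumerated distances and counted events.

    Returns (predictions, scores) as nested lists.
    """
    n = len(Xtr)
    Q = len(Ytr[0])
    priors = [
        (s + sum(Ytr[i][l] for i in range(n))) / (2 * s + n) for l in range(Q)
    ]
    # leave-one-out neighbour counts
    deltas = []
    for i in range(n):
        dist = sorted((( _ham(Xtr[i], Xtr[j]), j) for j in range(n) if j != i))
        nb = [j for _, j in dist[:k]]
        deltas.append([sum(Ytr[j][l] for j in nb) for l in range(Q)])
    like1, like0 = [], []
    for l in range(Q):
        c1 = [0] * (k + 1)
        c0 = [0] * (k + 1)
        for i in range(n):
            if Ytr[i][l] == 1:
                c1[deltas[i][l]] += 1
            else:
                c0[deltas[i][l]] += 1
        like1.append([(s + c) / (s * (k + 1) + sum(c1)) for c in c1])
        like0.append([(s + c) / (s * (k + 1) + sum(c0)) for c in c0])
    preds, scores = [], []
    for q in Xte:
        dist = sorted(((_ham(q, Xtr[j]), j) for j in range(n)))
        nb = [j for _, j in dist[:k]]
        row_p, row_s = [], []
        for l in range(Q):
            j = sum(Ytr[i][l] for i in nb)
            num = priors[l] * like1[l][j]
            den = num + (1 - priors[l]) * like0[l][j]
            post = num / den
            row_s.append(post)
            row_p.append(1 if post > 0.5 else 0)
        preds.append(row_p)
        scores.append(row_s)
    return preds, scores
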