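import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bruteforce import naive_cmi, naive_cmim, naive_entropy, naive_mi, naive_mrmr
from realml.data import Dataset
from realml.feature_selection import (
    ContingencyTable2x2,
    cmim_select,
    conditional_mutual_information,
    crosstab,
    information_gain,
    mrmr_select,
    mutual_information,
    rank_features,
    select_label_subspaces,
)

tables = st.tuples(
    st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30)
).filter(lambda t: sum(t) >= 1)


class TestCrosstab:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 1, 0, 0], [1, 0, 1, 0], (1, 1, 1, 1)),
            ([1, 1, 1], [1, 1, 1], (3, 0, 0, 0)),
            ([0], [1], (0, 0, 1, 0)),
        ],
    )
    def test_exact_joint_counts(self, x, y, expected):
        t = crosstab(x, y)
        assert (t.n11, t.n10, t.n01, t.n00) == expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            crosstab([1, 0], [1])


class TestInformationScores:
    def test_perfect_dependence_is_one_bit(self):
        assert mutual_information(ContingencyTable2x2(5, 0, 0, 5)) == pytest.approx(1.0)
        assert information_gain(ContingencyTable2x2(5, 0, 0, 5)) == pytest.approx(1.0)

    def test_independent_uniform_is_zero(self):
        assert mutual_information(ContingencyTable2x2(1, 1, 1, 1)) == pytest.approx(0.0)

    def test_constant_target_has_zero_gain(self):
        # x splits 4/6 but y is constant 1, so H(Y) = 0
        assert information_gain(ContingencyTable2x2(4, 0, 6, 0)) == 0.0

    def test_skewed_table_matches_entropy_difference(self):
        # H(0.4) - [0.4 H(0.75) + 0.6 H(1/6)]
        expected = naive_entropy([1] * 4 + [0] * 6) - (
            0.4 * naive_entropy([1, 1, 1, 0]) + 0.6 * naive_entropy([1, 0, 0, 0, 0, 0])
        )
        t = ContingencyTable2x2(3, 1, 1, 5)
        assert mutual_information(t) == pytest.approx(expected, abs=1e-12)
        assert mutual_information(t) == pytest.approx(0.25643, abs=1e-4)

    def test_against_sklearn_contingency(self):
        # independent library route (natural log, so divide by ln 2)
        from sklearn.metrics import mutual_info_score

        x = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
        y = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        expected = mutual_info_score(x, y) / math.log(2)
        assert mutual_information(crosstab(x, y)) == pytest.approx(expected, abs=1e-12)

    @given(tables)
    @settings(deadline=None, max_examples=200)
    def test_mi_equals_ig_on_every_table(self, counts):
        t = ContingencyTable2x2(*counts)
        assert mutual_information(t) == pytest.approx(
            information_gain(t), abs=1e-12
        )

    @given(tables)
    @settings(deadline=None, max_examples=200)
    def test_mi_bounded_by_marginal_entropies(self, counts):
        t = ContingencyTable2x2(*counts)
        n = t.n
        hx = naive_entropy([1] * (t.n11 + t.n10) + [0] * (t.n01 + t.n00))
        hy = naive_entropy([1] * (t.n11 + t.n01) + [0] * (t.n10 + t.n00))
        mi = mutual_information(t)
        assert 0.0 <= mi <= min(hx, hy) + 1e-12 <= 1.0 + 1e-12


class TestConditionalMI:
    def test_zero_when_target_determined_by_condition(self, rng):
        z = rng.integers(0, 2, 50)
        x = rng.integers(0, 2, 50)
        assert conditional_mutual_information(x, z, z) == pytest.approx(0.0)

    def test_constant_condition_reduces_to_mi(self, rng):
        x = rng.integers(0, 2, 40)
        y = rng.integers(0, 2, 40)
        z = np.zeros(40, dtype=int)
        assert conditional_mutual_information(x, y, z) == pytest.approx(
            mutual_information(crosstab(x, y)), abs=1e-12
        )

    def test_xor_has_one_bit_conditionally_but_zero_marginally(self):
        # equal replication of the 4-row (x, z) truth table with y = x xor z
        x = np.array([0, 0, 1, 1] * 5)
        z = np.array([0, 1, 0, 1] * 5)
        y = x ^ z
        assert conditional_mutual_information(x, y, z) == pytest.approx(1.0)
        assert mutual_information(crosstab(x, y)) == pytest.approx(0.0)

    def test_matches_naive_on_random_inputs(self, rng):
        for _ in range(20):
            x, y, z = (rng.integers(0, 2, 30) for _ in range(3))
            assert conditional_mutual_information(x, y, z) == pytest.approx(
                naive_cmi(list(x), list(y), list(z)), abs=1e-12
            )


class TestRankFeatures:
    def test_exact_copy_wins(self, rng):
        y = rng.integers(0, 2, 50)
        X = np.column_stack([y, rng.integers(0, 2, 50), rng.integers(0, 2, 50)])
        sub = rank_features(X, y, "mi", 1)
        assert sub.selected == [0]

    def test_full_selection_is_sorted_by_score(self, rng):
        y = rng.integers(0, 2, 50)
        X = rng.integers(0, 2, (50, 6))
        sub = rank_features(X, y, "ig", 6)
        assert len(sub.selected) == 6
        assert all(a >= b for a, b in zip(sub.scores, sub.scores[1:]))

    def test_identical_columns_tie_break_to_lower_index(self, rng):
        y = rng.integers(0, 2, 30)
        noise = rng.integers(0, 2, 30)
        X = np.column_stack([noise, y, y])
        sub = rank_features(X, y, "mi", 1)
        assert sub.selected == [1]

    def test_m_larger_than_d_clips(self, rng):
        X = rng.integers(0, 2, (20, 3))
        y = rng.integers(0, 2, 20)
        sub = rank_features(X, y, "ig", 10)
        assert len(sub.selected) == 3

    def test_row_permutation_invariance(self, rng):
        X = rng.integers(0, 2, (40, 5))
        y = rng.integers(0, 2, 40)
        perm = rng.permutation(40)
        a = rank_features(X, y, "ig", 5)
        b = rank_features(X[perm], y[perm], "ig", 5)
        assert a.selected == b.selected
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-12)

    def test_direction_sign_reported(self):
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        pos = np.array([1, 1, 1, 0, 0, 0, 0, 0])   # fires with y
        neg = 1 - pos                              # fires against y
        sub = rank_features(np.column_stack([pos, neg]), y, "mi", 2)
        signs = dict(zip(sub.selected, sub.directions))
        assert signs[0] == 1 and signs[1] == -1


class TestCmimSelect:
    def test_duplicate_column_scored_zero_conditionally(self):
        # strongest feature is a near-copy of y; its exact duplicate adds
        # zero conditional information while a weaker novel feature does not
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 60)
        strong = np.where(rng.random(60) < 0.9, y, 1 - y)
        weak = np.where(rng.random(60) < 0.75, y, 1 - y)
        X = np.column_stack([strong, strong, weak])
        sub = cmim_select(X, y, 2)
        assert sub.selected == naive_cmim(X.tolist(), list(y), 2) == [0, 2]
        assert sub.scores[1] > 0

    def test_single_pick_equals_mi_ranking(self, rng):
        X = rng.integers(0, 2, (40, 5))
        y = rng.integers(0, 2, 40)
        assert cmim_select(X, y, 1).selected == rank_features(X, y, "mi", 1).selected

    def test_all_identical_columns(self, rng):
        y = rng.integers(0, 2, 30)
        X = np.tile(y[:, None], (1, 4))
        sub = cmim_select(X, y, 4)
        assert sub.selected == [0, 1, 2, 3]
        assert all(s == pytest.approx(0.0, abs=1e-12) for s in sub.scores[1:])

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_exhaustive_greedy(self, seed):
        rng = np.random.default_rng(seed)
        n, d, m = 25, rng.integers(3, 9), 4
        X = rng.integers(0, 2, (n, d))
        y = rng.integers(0, 2, n)
        got = cmim_select(X, y, min(m, d)).selected
        expected = naive_cmim(X.tolist(), list(y), min(m, d))
        assert got == expected


class TestMrmrSelect:
    def test_duplicate_penalised_novel_weak_feature_preferred(self):
        # strongest feature is a near-copy of y; its duplicate carries full
        # redundancy while a weak but novel feature keeps positive score
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 80)
        strong = np.where(rng.random(80) < 0.95, y, 1 - y)
        weak = np.where(rng.random(80) < 0.7, y, rng.integers(0, 2, 80))
        X = np.column_stack([strong, strong, weak])
        sub = mrmr_select(X, y, 2)
        assert sub.selected == naive_mrmr(X.tolist(), list(y), 2) == [0, 2]
        assert sub.scores[1] > 0

    def test_single_pick_is_argmax_mi(self, rng):
        X = rng.integers(0, 2, (40, 5))
        y = rng.integers(0, 2, 40)
        assert mrmr_select(X, y, 1).selected == rank_features(X, y, "mi", 1).selected

    def test_orthogonal_design_reduces_to_relevance_order(self):
        # full 3-bit factorial: pairwise feature MI is exactly zero, so the
        # greedy order must equal the pure-relevance (univariate MI) order
        X = np.array([[b >> 2 & 1, b >> 1 & 1, b & 1] for b in range(8)])
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0])  # mostly follows bit 2
        for i in range(3):
            for j in range(i + 1, 3):
                assert naive_mi(list(X[:, i]), list(X[:, j])) == pytest.approx(0.0)
        relevance_order = list(
            np.argsort([-naive_mi(list(X[:, j]), list(y)) for j in range(3)],
                       kind="stable")
        )
        assert mrmr_select(X, y, 3).selected == relevance_order

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_exhaustive_greedy(self, seed):
        rng = np.random.default_rng(100 + seed)
        n, d, m = 25, rng.integers(3, 9), 4
        X = rng.integers(0, 2, (n, d))
        y = rng.integers(0, 2, n)
        got = mrmr_select(X, y, min(m, d)).selected
        expected = naive_mrmr(X.tolist(), list(y), min(m, d))
        assert got == expected


class TestSelectLabelSubspaces:
    def test_each_label_finds_its_own_feature(self, rng):
        X = rng.integers(0, 2, (50, 4))
        Y = np.column_stack([X[:, 2], X[:, 0]])
        ds = Dataset(X, Y)
        subs = select_label_subspaces(ds, "ig", 1)
        assert subs[0].selected == [2]
        assert subs[1].selected == [0]

    def test_full_m_returns_every_feature(self, random_dataset):
        subs = select_label_subspaces(random_dataset, "mi", random_dataset.n_features)
        for sub in subs:
            assert sorted(sub.selected) == list(range(random_dataset.n_features))

    @pytest.mark.parametrize("method", ["mi", "ig", "cmim", "mrmr"])
    def test_all_methods_produce_valid_subspaces(self, random_dataset, method):
        subs = select_label_subspaces(random_dataset, method, 4)
        assert len(subs) == random_dataset.n_labels
        for sub in subs:
            assert len(sub.selected) == 4
            assert len(set(sub.selected)) == 4
            assert all(np.isfinite(sub.scores))
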