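"""TOPSIS: normalization, ideal points, separations, closeness and ranking,
cross-checked against an independent scripted recomputation."""

import math

import numpy as np
import pytest

from adrank import (CriterionDirection, DecisionMatrix, WeightVector,
                    closeness_coefficient, entropy_weight_vector, ideal_points,
                    separation_measures, topsis_rank, vector_normalize,
                    weight_matrix)
from adrank.topsis import DegenerateInstanceError, rank_descending

from conftest import random_positive_matrix


def scripted_topsis(x, w, is_benefit):
    """From-scratch pure-python TOPSIS oracle (no shared code path)."""
    m, n = len(x), len(x[0])
    norms = [math.sqrt(sum(x[i][j] ** 2 for i in range(m))) for j in range(n)]
    v = [[w[j] * x[i][j] / norms[j] for j in range(n)] for i in range(m)]
    ideal = [max(v[i][j] for i in range(m)) if is_benefit[j]
             else min(v[i][j] for i in range(m)) for j in range(n)]
    anti = [min(v[i][j] for i in range(m)) if is_benefit[j]
            else max(v[i][j] for i in range(m)) for j in range(n)]
    pp = [math.sqrt(sum((v[i][j] - ideal[j]) ** 2 for j in range(n))) for i in range(m)]
    pm = [math.sqrt(sum((v[i][j] - anti[j]) ** 2 for j in range(n))) for i in range(m)]
    close = [pm[i] / (pp[i] + pm[i]) for i in range(m)]
    order = sorted(range(m), key=lambda i: -close[i])
    ranks = [0] * m
    for pos, i in enumerate(order):
        ranks[i] = pos + 1
    return close, ranks


class TestStages:
    def test_three_four_five_column(self):
        D = DecisionMatrix(["a", "b"], ["C1"], [[3.0], [4.0]])
        assert vector_normalize(D)[:, 0] == pytest.approx([0.6, 0.8])

    def test_constant_column_normalizes_to_inverse_sqrt_m(self):
        D = DecisionMatrix(["a", "b", "c", "d"], ["C1"], [[5.0]] * 4)
        assert vector_normalize(D)[:, 0] == pytest.approx([0.5] * 4)

    @pytest.mark.parametrize("seed", range(5))
    def test_column_norms_are_one(self, seed):
        R = vector_normalize(random_positive_matrix(12, 6, seed))
        assert (R ** 2).sum(axis=0) == pytest.approx(np.ones(6), abs=1e-12)

    def test_weighting_is_columnwise_product(self):
        R = np.arange(6, dtype=float).reshape(2, 3) + 1
        W = WeightVector(["C1", "C2", "C3"], [1.0, 0.0, 0.0])
        V = weight_matrix(R, W)
        assert V[:, 0] == pytest.approx(R[:, 0])
        assert np.all(V[:, 1:] == 0)

    def test_ideal_points_flip_with_direction(self):
        V = np.array([[0.1], [0.3], [0.2]])
        ideal, anti = ideal_points(V, CriterionDirection(["C1"], ["benefit"]))
        assert (ideal[0], anti[0]) == (0.3, 0.1)
        ideal, anti = ideal_points(V, CriterionDirection(["C1"], ["cost"]))
        assert (ideal[0], anti[0]) == (0.1, 0.3)

    def test_constant_column_ideal_equals_anti_ideal(self):
        V = np.full((3, 1), 0.4)
        ideal, anti = ideal_points(V, CriterionDirection.all_benefit(["C1"]))
        assert ideal[0] == anti[0]

    def test_separation_single_criterion_is_absolute_difference(self):
        pp, pm = separation_measures(np.array([[0.2]]), np.array([0.5]), np.array([0.1]))
        assert (pp[0], pm[0]) == pytest.approx((0.3, 0.1))

    def test_row_equal_to_ideal_has_zero_p_plus(self):
        V = np.array([[0.5, 0.2], [0.1, 0.1]])
        pp, _ = separation_measures(V, np.array([0.5, 0.2]), np.array([0.0, 0.0]))
        assert pp[0] == 0

    @pytest.mark.parametrize("pp,pm,expected", [
        ((0.0, 0.4), None, 1.0),
        ((0.4, 0.0), None, 0.0),
        ((0.3, 0.3), None, 0.5),
    ])
    def test_closeness_limits(self, pp, pm, expected):
        assert closeness_coefficient([pp[0]], [pp[1]])[0] == pytest.approx(expected)

    def test_degenerate_instance_raises(self):
        with pytest.raises(DegenerateInstanceError):
            closeness_coefficient([0.0], [0.0])


class TestRanking:
    def test_competition_ranking_with_ties(self):
        ranks, ties = rank_descending(np.array([0.9, 0.5, 0.9, 0.1]))
        assert list(ranks) == [1, 3, 1, 4]
        assert ties == [[0, 2]]

    def test_dominant_alternative_gets_rank_one_closeness_one(self):
        vals = np.array([[9.0, 9.0, 9.0], [1.0, 2.0, 3.0], [2.0, 1.0, 2.0]])
        D = DecisionMatrix(["top", "a", "b"], ["C1", "C2", "C3"], vals)
        res = topsis_rank(D, WeightVector.equal(D.criteria))
        i = D.alternatives.index("top")
        assert res.closeness[i] == pytest.approx(1.0)
        assert res.ranks[i] == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_closeness_in_unit_interval(self, seed):
        D = random_positive_matrix(12, 6, seed)
        res = topsis_rank(D, entropy_weight_vector(D))
        assert np.all((res.closeness >= 0) & (res.closeness <= 1))
        assert sorted(res.ranks) == list(range(1, 13))

    @pytest.mark.parametrize("seed", range(5))
    def test_scale_invariance_of_ranks_and_closeness(self, seed):
        D = random_positive_matrix(12, 6, seed)
        W = entropy_weight_vector(D)
        scale = np.array([10.0, 1.0, 0.2, 5.0, 1.0, 100.0])
        D2 = DecisionMatrix(D.alternatives, D.criteria, D.values * scale)
        r1 = topsis_rank(D, W)
        r2 = topsis_rank(D2, entropy_weight_vector(D2))
        assert r2.closeness == pytest.approx(r1.closeness, abs=1e-9)
        assert list(r2.ranks) == list(r1.ranks)

    def test_direction_reversal_swaps_two_alternative_ranking(self):
        D = DecisionMatrix(["a", "b"], ["C1"], [[1.0], [2.0]])
        W = WeightVector(["C1"], [1.0])
        benefit = topsis_rank(D, W, CriterionDirection(["C1"], ["benefit"]))
        cost = topsis_rank(D, W, CriterionDirection(["C1"], ["cost"]))
        assert list(benefit.ranks) == [2, 1]
        assert list(cost.ranks) == [1, 2]

    def test_permuting_rows_permutes_closeness(self):
        D = random_positive_matrix(8, 4, 42)
        W = entropy_weight_vector(D)
        perm = np.random.default_rng(0).permutation(8)
        Dp = DecisionMatrix([D.alternatives[i] for i in perm], D.criteria,
                            D.values[perm])
        res, resp = topsis_rank(D, W), topsis_rank(Dp, W)
        assert resp.closeness == pytest.approx(res.closeness[perm])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_scripted_oracle_on_random_instances(self, seed):
        """20 seeded 12x6 instances, mixed directions, vs the from-scratch
        pure-python recomputation."""
        rng = np.random.default_rng(1000 + seed)
        D = random_positive_matrix(12, 6, 1000 + seed)
        w = rng.dirichlet(np.ones(6))
        is_benefit = rng.integers(0, 2, size=6).astype(bool)
        W = WeightVector(D.criteria, w)
        direction = CriterionDirection(
            D.criteria, ["benefit" if b else "cost" for b in is_benefit])
        res = topsis_rank(D, W, direction)
        close, ranks = scripted_topsis(D.values.tolist(), list(w), list(is_benefit))
        assert res.closeness == pytest.approx(np.array(close), abs=1e-12)
        assert list(res.ranks) == ranks
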