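"""MRMR: discretization, MI estimator, greedy selection, aggregation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import mutual_info_score

from emoeeg.selection import (
    DiscretizedFeatures,
    aggregate_top_electrodes,
    discretize,
    mrmr_rank,
    mutual_information,
)


class TestDiscretize:
    def test_mu_sigma_three_levels(self):
        d = discretize(np.array([[-10.0], [0.0], [10.0]]))
        assert list(d.codes[:, 0]) == [0, 1, 2]
        assert not d.constant[0]

    def test_constant_feature_flagged(self):
        d = discretize(np.full((5, 1), 3.14))
        assert d.constant[0]
        assert set(d.codes[:, 0]) == {0}

    def test_equal_frequency_occupancy(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3000, 1))
        d = discretize(x, n_levels=3, method="quantile")
        occ = np.bincount(d.codes[:, 0], minlength=3) / 3000
        assert np.all(np.abs(occ - 1 / 3) < 0.05)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            discretize(np.zeros((3, 1)), n_levels=1)
        with pytest.raises(ValueError):
            discretize(np.zeros((3, 1)), n_levels=4, method="mu_sigma")


class TestMutualInformation:
    def test_self_information_is_entropy(self):
        x = np.repeat([0, 1, 2], 30)
        assert mutual_information(x, x) == pytest.approx(np.log(3))

    def test_independent_uniform_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, 10_000)
        y = rng.integers(0, 3, 10_000)
        assert mutual_information(x, y) < 0.01

    def test_constant_gives_zero_and_symmetry(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 3, 100)
        assert mutual_information(np.zeros(100, dtype=int), y) == 0.0
        x = rng.integers(0, 4, 100)
        assert mutual_information(x, y) == pytest.approx(mutual_information(y, x))

    def test_closed_form_dependent_table(self):
        # perfectly dependent 2x2 with uniform margins -> log 2
        x = np.array([0, 1] * 50)
        assert mutual_information(x, 1 - x) == pytest.approx(np.log(2))

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 3, 500)
        y = (x + rng.integers(0, 2, 500)) % 3
        assert mutual_information(x, y) == pytest.approx(mutual_info_score(x, y))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mutual_information(np.zeros(3), np.zeros(4))


def brute_force_mrmr(codes: np.ndarray, y: np.ndarray, k: int) -> list[int]:
    """Literal greedy forward selection, recomputing the criterion from
    scratch with pairwise MI at every step."""
    p = codes.shape[1]
    selected: list[int] = []
    for _ in range(k):
        best, best_val = None, -np.inf
        for j in range(p):
            if j in selected:
                continue
            rel = mutual_information(codes[:, j], y)
            red = (
                np.mean([mutual_information(codes[:, j], codes[:, i]) for i in selected])
                if selected
                else 0.0
            )
            val = rel - red
            if val > best_val + 1e-12:
                best, best_val = j, val
        selected.append(best)
    return selected


class TestMrmr:
    def _random_problem(self, rng, n=120, p=6):
        y = rng.integers(0, 3, n)
        codes = np.empty((n, p), dtype=int)
        for j in range(p):
            noise = rng.integers(0, 3, n)
            keep = rng.random(n) < rng.random()
            codes[:, j] = np.where(keep, y, noise)
        return codes, y

    def test_matches_brute_force_on_random_problems(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            codes, y = self._random_problem(rng)
            disc = DiscretizedFeatures(codes, [], 3, np.zeros(codes.shape[1], bool))
            ranking = mrmr_rank(disc, y)
            assert list(ranking.order) == brute_force_mrmr(codes, y, codes.shape[1])

    def test_k1_selects_max_relevance(self):
        rng = np.random.default_rng(0)
        codes, y = self._random_problem(rng)
        disc = DiscretizedFeatures(codes, [], 3, np.zeros(codes.shape[1], bool))
        ranking = mrmr_rank(disc, y, k=1)
        rel = [mutual_information(codes[:, j], y) for j in range(codes.shape[1])]
        assert ranking.order[0] == int(np.argmax(rel))

    def test_duplicate_of_top_feature_not_second(self):
        rng = np.random.default_rng(7)
        n = 300
        y = rng.integers(0, 3, n)
        top = np.where(rng.random(n) < 0.8, y, rng.integers(0, 3, n))
        other = np.where(rng.random(n) < 0.5, y, rng.integers(0, 3, n))
        codes = np.column_stack([top, top.copy(), other])
        disc = DiscretizedFeatures(codes, [], 3, np.zeros(3, bool))
        ranking = mrmr_rank(disc, y)
        assert ranking.order[0] == 0
        assert ranking.order[1] == 2  # the duplicate is fully redundant

    def test_zero_redundancy_weight_sorts_by_relevance(self):
        rng = np.random.default_rng(1)
        codes, y = self._random_problem(rng)
        disc = DiscretizedFeatures(codes, [], 3, np.zeros(codes.shape[1], bool))
        ranking = mrmr_rank(disc, y, redundancy_weight=0.0)
        rel = ranking.relevance
        assert list(ranking.order) == sorted(range(len(rel)), key=lambda j: (-rel[j], j))

    def test_bad_k_raises(self):
        disc = DiscretizedFeatures(np.zeros((10, 3), int), [], 3, np.zeros(3, bool))
        with pytest.raises(ValueError):
            mrmr_rank(disc, np.zeros(10, int), k=0)


class TestAggregation:
    def _ranking(self, order, p=6, names=None):
        from emoeeg.selection import FeatureRanking

        order = np.asarray(order)
        return FeatureRanking(
            order=order,
            scores=np.zeros(len(order)),
            relevance=np.zeros(p),
            names=names or [f"C{j}_DE_gamma" for j in range(p)],
        )

    def test_single_subject_returns_own_list(self):
        r = self._ranking([3, 1, 0, 2])
        agg = aggregate_top_electrodes([r], top_n=4)
        assert list(agg["feature"]) == [f"C{j}_DE_gamma" for j in (3, 1, 0, 2)]

    def test_identical_rankings_aggregate_unchanged(self):
        r = self._ranking([5, 2, 4])
        agg = aggregate_top_electrodes([r, r, r], top_n=3)
        assert list(agg["feature"]) == [f"C{j}_DE_gamma" for j in (5, 2, 4)]
        assert list(agg["n_subjects"]) == [3, 3, 3]

    def test_majority_feature_wins(self):
        a = self._ranking([0, 1])
        b = self._ranking([0, 2])
        agg = aggregate_top_electrodes([a, b], top_n=2)
        assert agg["feature"].iloc[0] == "C0_DE_gamma"

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            aggregate_top_electrodes([], top_n=1)
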