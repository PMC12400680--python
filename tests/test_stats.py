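"""Rank correlations, dependent-correlation bootstrap, and rank tests."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from bcsagree.stats import (
    UndefinedCorrelationError,
    bootstrap_dependent_rho_diff,
    correlation_matrix,
    fisher_exact_2x2,
    mann_whitney_u,
    spearman_rho,
    wilcoxon_signed_rank,
)


def rank_then_pearson(x, y) -> float:
    """Oracle: mid-rank both vectors, then plain product-moment correlation."""
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearman:
    def test_monotone_is_one(self):
        assert spearman_rho([1, 2, 3, 4], [2, 4, 6, 8]).rho == pytest.approx(1.0)

    def test_classic_formula_value(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with sum(d^2) = 2
        assert spearman_rho([1, 2, 3, 4], [1, 3, 2, 4]).rho == pytest.approx(0.8)

    def test_matches_rank_then_pearson_with_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 30))
            x = rng.integers(1, 6, size=n).astype(float)
            y = x + rng.integers(-1, 2, size=n)
            if np.unique(x).size < 2 or np.unique(y).size < 2:
                continue
            assert spearman_rho(x, y).rho == pytest.approx(rank_then_pearson(x, y))

    def test_invariant_under_monotone_transform(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        r0 = spearman_rho(x, y).rho
        assert spearman_rho(np.exp(x), y).rho == pytest.approx(r0)
        assert spearman_rho(x, y**3).rho == pytest.approx(r0)

    def test_pairwise_deletion(self):
        x = [1, 2, np.nan, 4, 5]
        y = [2, 4, 6, np.nan, 10]
        assert spearman_rho(x, y).n == 3

    def test_zero_variance_errors(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])


class TestCorrelationMatrix:
    def test_identical_and_negated_columns(self):
        cols = {"a": [1, 2, 3, 4], "b": [1, 2, 3, 4], "c": [4, 3, 2, 1]}
        res = correlation_matrix(cols)
        assert res.rho.loc["a", "b"] == pytest.approx(1.0)
        assert res.rho.loc["a", "c"] == pytest.approx(-1.0)
        assert list(np.diag(res.rho)) == [1.0, 1.0, 1.0]
        assert res.names == ["a", "b", "c"]

    def test_symmetry_and_undefined_cells(self):
        cols = {"a": [1, 2, 3, 4], "b": [2, 1, 4, 3], "const": [5, 5, 5, 5]}
        res = correlation_matrix(cols)
        assert res.rho.loc["a", "b"] == res.rho.loc["b", "a"]
        assert np.isnan(res.rho.loc["a", "const"])


class TestBootstrapRhoDiff:
    def test_self_comparison_is_null(self):
        x = np.arange(10.0)
        y = np.array([2, 1, 4, 3, 6, 5, 8, 7, 9, 10.0])
        res = bootstrap_dependent_rho_diff(x, y, y, replicates=200, seed=7)
        assert res.delta == 0.0
        assert res.ci == (0.0, 0.0)
        assert res.p_value == 1.0

    def test_bit_reproducible_from_seed(self, rng):
        x, y1, y2 = rng.normal(size=(3, 30))
        a = bootstrap_dependent_rho_diff(x, y1, y2, replicates=300, seed=11)
        b = bootstrap_dependent_rho_diff(x, y1, y2, replicates=300, seed=11)
        assert a == b
        c = bootstrap_dependent_rho_diff(x, y1, y2, replicates=300, seed=12)
        assert a.ci != c.ci

    def test_power_detects_clear_difference(self, rng):
        n = 200
        truth = rng.normal(size=n)
        y1 = truth + 0.3 * rng.normal(size=n)
        y2 = rng.normal(size=n)  # independent noise
        res = bootstrap_dependent_rho_diff(truth, y1, y2, replicates=500, seed=3)
        assert res.ci[0] > 0  # CI excludes 0

    def test_preconditions(self):
        with pytest.raises(ValueError):
            bootstrap_dependent_rho_diff([1, 2, 3], [1, 2, 3], [3, 2, 1], seed=1)
        with pytest.raises(UndefinedCorrelationError):
            bootstrap_dependent_rho_diff(
                [1, 2, 3, 4, 5], [1, 1, 1, 1, 1], [1, 2, 3, 4, 5], seed=1
            )
        with pytest.raises(ValueError):
            bootstrap_dependent_rho_diff(
                [1, 2, 3, 4, 5], [2, 1, 3, 5, 4], [1, 2, 3, 4, 5], replicates=50, seed=1
            )


def exact_signed_rank_p(d) -> float:
    """Full 2^n enumeration of the signed-rank null (mid-ranks, two-sided)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    r = sps.rankdata(np.abs(d))
    t_obs = r[d > 0].sum()
    sums = []
    for signs in itertools.product([False, True], repeat=len(d)):
        sums.append(sum(ri for ri, s in zip(r, signs) if s))
    sums = np.array(sums)
    return min(1.0, 2 * min((sums <= t_obs + 1e-9).mean(), (sums >= t_obs - 1e-9).mean()))


def exact_mwu_p(a, b) -> float:
    """Enumeration over all group assignments of the pooled sample."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
    us = np.array(us)
    return min(1.0, 2 * min((us <= u_obs + 1e-9).mean(), (us >= u_obs - 1e-9).mean()))


class TestWilcoxon:
    def test_identical_samples_degenerate(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0

    def test_unit_shift_exact_tail(self):
        a = np.arange(1.0, 11.0)
        res = wilcoxon_signed_rank(a + 1, a)
        assert res.p_value == pytest.approx(2 / 2**10)

    def test_matches_enumeration_with_and_without_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 11))
            d = np.round(rng.normal(scale=2.0, size=n))
            if (d != 0).sum() < 2:
                continue
            ours = wilcoxon_signed_rank(d, np.zeros_like(d)).p_value
            assert ours == pytest.approx(exact_signed_rank_p(d))


class TestMannWhitney:
    def test_identical_groups(self):
        assert mann_whitney_u([1, 2, 3], [1, 2, 3]).p_value > 0.99

    def test_complete_separation_exact(self):
        res = mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2 / C(6,3)

    def test_matches_enumeration_small_samples(self, rng):
        for _ in range(15):
            na, nb = int(rng.integers(3, 6)), int(rng.integers(3, 6))
            a = rng.normal(size=na)
            b = rng.normal(size=nb) + 0.5
            assert mann_whitney_u(a, b).p_value == pytest.approx(exact_mwu_p(a, b))

    def test_group_swap_symmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=6) + 1
        assert mann_whitney_u(a, b).p_value == pytest.approx(mann_whitney_u(b, a).p_value)


class TestFisherExact:
    def test_homogeneous_table(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_perfect_association(self):
        assert fisher_exact_2x2([[10, 0], [0, 10]]).p_value == pytest.approx(
            2 / math.comb(20, 10)
        )

    def test_hypergeometric_enumeration(self):
        # sum of P(k) over tables with P(k) <= P(observed): k in {0, 1, 9, 10}
        pk = [math.comb(10, k) * math.comb(10, 10 - k) / math.comb(20, 10) for k in range(11)]
        expected = sum(p for p in pk if p <= pk[1] + 1e-15)
        assert fisher_exact_2x2([[1, 9], [9, 1]]).p_value == pytest.approx(expected)

    def test_zero_margin_degenerate(self):
        with pytest.warns(UserWarning):
            res = fisher_exact_2x2([[0, 0], [3, 4]])
        assert res.p_value == 1.0
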