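"""Deviation statistics, Kendall's W (with brute-force oracle), Bland-Altman."""

import numpy as np
import pytest

from bcsagree.agreement import (
    ReferenceKey,
    bland_altman,
    deviation_summary,
    kendalls_w,
    signed_deviation,
)
from bcsagree.io import ScoreMatrix
from conftest import random_score_matrix


def brute_force_kendalls_w(columns: list[list[float]]) -> float:
    """Textbook ties-corrected W computed with hand-rolled mid-ranks.

    Independent of the package implementation (pure Python, no scipy).
    """

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    m = len(columns)
    n = len(columns[0])
    ranked = [midranks(col) for col in columns]
    rank_sums = [sum(ranked[j][i] for j in range(m)) for i in range(n)]
    mean = sum(rank_sums) / n
    S = sum((r - mean) ** 2 for r in rank_sums)
    T = 0.0
    for col in columns:
        for v in set(col):
            t = col.count(v)
            T += t**3 - t
    return 12.0 * S / (m**2 * (n**3 - n) - m * T)


class TestSignedDeviation:
    @pytest.mark.parametrize(
        "score,key,expected",
        [
            (6, {6}, 0),
            (7, {5, 6}, 1),  # nearest key 6
            (6, {5, 7}, 1),  # equidistant -> lower key 5 -> +1
            (3, {5, 6}, -2),
            (5, {5, 6}, 0),
        ],
    )
    def test_closest_key_rule(self, score, key, expected):
        rk = ReferenceKey("s", frozenset(key))
        assert signed_deviation(score, rk) == expected

    def test_empty_key_rejected(self):
        with pytest.raises(ValueError):
            ReferenceKey("s", frozenset())


class TestDeviationSummary:
    def test_self_comparison_is_zero(self, small_matrix):
        keys = {
            s: ReferenceKey.single(s, small_matrix.row(s)["A"])
            for s in small_matrix.subjects
        }
        summary = deviation_summary(small_matrix, keys, raters=["A"])
        assert summary.mean_abs == 0.0
        assert summary.complete_agreement_fraction == 1.0

    def test_hand_computed_two_subject_case(self):
        m = ScoreMatrix.from_dict({"A": [5, 7]}, subjects=["s1", "s2"])
        keys = {"s1": ReferenceKey.single("s1", 5), "s2": ReferenceKey.single("s2", 6)}
        summary = deviation_summary(m, keys)
        assert summary.mean_abs == pytest.approx(0.5)
        assert summary.distribution == {0: 0.5, 1: 0.5}
        assert summary.n == 2

    def test_sem_matches_pooled_sample_sd(self):
        m = ScoreMatrix.from_dict({"A": [5, 7, 6], "B": [6, 6, 6]})
        keys = {s: ReferenceKey.single(s, 6) for s in m.subjects}
        summary = deviation_summary(m, keys)
        abs_devs = [1, 1, 0, 0, 0, 0]
        assert summary.sem == pytest.approx(np.std(abs_devs, ddof=1) / np.sqrt(6))

    def test_no_evaluations_errors(self, small_matrix):
        keys = {s: ReferenceKey.single(s, 5) for s in small_matrix.subjects}
        with pytest.raises(KeyError):
            deviation_summary(small_matrix, keys, raters=["nope"])


class TestKendallsW:
    def test_perfect_concordance(self):
        m = ScoreMatrix.from_dict({"A": [1, 3, 5, 7, 9], "B": [2, 4, 5, 8, 9], "C": [1, 2, 3, 4, 5]})
        res = kendalls_w(m)
        assert res.W == pytest.approx(1.0)
        assert res.df == 4

    def test_hand_derived_one_ninth(self):
        m = ScoreMatrix.from_dict({"A": [1, 2, 3], "B": [3, 2, 1], "C": [2, 1, 3]})
        assert kendalls_w(m).W == pytest.approx(1 / 9)

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(50):
            n, m = int(rng.integers(3, 7)), int(rng.integers(2, 6))
            mat = random_score_matrix(rng, n, m)
            cols = [
                [float(v) for v in mat.frame[r].tolist()] for r in mat.raters
            ]
            try:
                ours = kendalls_w(mat).W
            except ValueError:
                continue  # fully tied degenerate draw
            assert ours == pytest.approx(brute_force_kendalls_w(cols))

    def test_invariant_under_monotone_column_transform(self, rng):
        mat = random_score_matrix(rng, 8, 4)
        w0 = kendalls_w(mat).W
        frame = mat.frame.astype("Float64")
        frame["r0"] = frame["r0"] * 3 + 2  # strictly monotone: ranks unchanged
        w1 = kendalls_w(ScoreMatrix(frame, validate=False)).W
        assert w1 == pytest.approx(w0)

    def test_chi_square_and_p(self):
        m = ScoreMatrix.from_dict({"A": [1, 2, 3, 4], "B": [1, 2, 4, 3]})
        res = kendalls_w(m)
        assert res.chi_square == pytest.approx(res.n_raters * (res.n_subjects - 1) * res.W)
        assert 0 <= res.p_value <= 1

    def test_constant_raters_degenerate(self):
        m = ScoreMatrix.from_dict({"A": [5, 5, 5], "B": [5, 5, 5]})
        with pytest.raises(ValueError, match="degenerate"):
            kendalls_w(m)


class TestBlandAltman:
    def test_identical_series(self):
        res = bland_altman([1, 2, 3], [1, 2, 3])
        assert res.mean_difference == 0 and res.limits == (0, 0)

    def test_constant_offset(self):
        res = bland_altman([2, 3, 4], [1, 2, 3])
        assert res.mean_difference == pytest.approx(1.0)
        assert res.sd_difference == pytest.approx(0.0)

    def test_hand_computed_case(self):
        res = bland_altman([1, 2, 3], [1, 1, 1])
        assert res.mean_difference == pytest.approx(1.0)
        assert res.sd_difference == pytest.approx(1.0)
        assert res.limits == (pytest.approx(-0.96), pytest.approx(2.96))
        assert list(res.points["mean"]) == [1.0, 1.5, 2.0]

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=10)
        assert bland_altman(a, b).mean_difference == pytest.approx(
            -bland_altman(b, a).mean_difference
        )

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            bland_altman([1], [2])
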