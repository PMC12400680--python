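"""Correlation and non-parametric inference for rater-score comparisons.

Spearman rank correlations (mid-ranks, t-approximation p-values), pairwise
correlation matrices with pairwise deletion, and the subject-level bootstrap
comparison of two *dependent overlapping* Spearman correlations — two
correlations rho(x, y1) and rho(x, y2) sharing the variable x measured on
the same subjects.  Subjects (rows) are resampled with replacement so the
dependence between y1 and y2 is preserved through the shared index; the
two-sided p-value is the symmetric sign-crossing proportion of the
replicate deltas and the confidence interval is the percentile interval.

Also provides the rank tests used when comparing deviation distributions:
Wilcoxon signed-rank (exact null for <= 25 untied nonzero differences,
tie/continuity-corrected normal approximation otherwise), Mann-Whitney U
(exact for small untied samples), and Fisher's exact test on 2x2 tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "CorrelationMatrixResult",
    "BootstrapComparison",
    "TestResult",
    "UndefinedCorrelationError",
    "spearman_rho",
    "correlation_matrix",
    "bootstrap_dependent_rho_diff",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "fisher_exact_2x2",
]


class UndefinedCorrelationError(ValueError):
    """Raised when a rank vector has zero variance."""


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (equal length)")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman's rank-order correlation with mid-ranks for ties.

    Missing pairs are deleted pairwise; requires n >= 3 complete pairs.
    The p-value uses the t approximation on n - 2 degrees of freedom.
    """
    xv, yv = _pairwise_complete(x, y)
    n = xv.size
    if n < 3:
        raise ValueError(f"spearman_rho requires >= 3 complete pairs, got {n}")
    if np.unique(xv).size < 2 or np.unique(yv).size < 2:
        raise UndefinedCorrelationError("zero variance in a rank vector")
    rho, p = sps.spearmanr(xv, yv)
    return CorrelationResult(rho=float(rho), p_value=float(p), n=int(n))


@dataclass
class CorrelationMatrixResult:
    """Pairwise Spearman correlations among named columns.

    ``rho``/``p``/``n`` are square DataFrames in the input column order with
    unit diagonal; cells with fewer than 3 complete pairs or zero variance
    are NaN (undefined).
    """

    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    @property
    def names(self) -> list[str]:
        return list(self.rho.columns)


def correlation_matrix(
    columns: Mapping[str, Sequence[float]] | pd.DataFrame,
) -> CorrelationMatrixResult:
    """Symmetric Spearman correlation matrix with pairwise deletion."""
    df = pd.DataFrame(columns).astype(float)
    if df.shape[1] < 2:
        raise ValueError("correlation_matrix requires >= 2 columns")
    names = list(df.columns)
    k = len(names)
    rho = pd.DataFrame(np.eye(k), index=names, columns=names)
    p = pd.DataFrame(np.full((k, k), np.nan), index=names, columns=names)
    nmat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i in range(k):
        nmat.iloc[i, i] = int(df.iloc[:, i].notna().sum())
        for j in range(i + 1, k):
            try:
                res = spearman_rho(df.iloc[:, i], df.iloc[:, j])
            except (ValueError, UndefinedCorrelationError):
                rho.iloc[i, j] = rho.iloc[j, i] = np.nan
                continue
            rho.iloc[i, j] = rho.iloc[j, i] = res.rho
            p.iloc[i, j] = p.iloc[j, i] = res.p_value
            nmat.iloc[i, j] = nmat.iloc[j, i] = res.n
    return CorrelationMatrixResult(rho=rho, p=p, n=nmat)


@dataclass(frozen=True)
class BootstrapComparison:
    """Bootstrap comparison of two overlapping dependent Spearman rho's."""

    rho_1: float
    rho_2: float
    delta: float
    ci: tuple[float, float]
    p_value: float
    replicates: int
    level: float
    seed: int
    n: int
    n_redrawn: int


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return sps.rankdata(a, axis=1)


def _row_corr(ra: np.ndarray, rb: np.ndarray) -> np.ndarray:
    """Pearson correlation of each paired row of two rank matrices."""
    ca = ra - ra.mean(axis=1, keepdims=True)
    cb = rb - rb.mean(axis=1, keepdims=True)
    num = (ca * cb).sum(axis=1)
    den = np.sqrt((ca**2).sum(axis=1) * (cb**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def bootstrap_dependent_rho_diff(
    x: Sequence[float],
    y1: Sequence[float],
    y2: Sequence[float],
    replicates: int = 5000,
    level: float = 0.95,
    seed: int | None = None,
) -> BootstrapComparison:
    """Compare rho(x, y1) with rho(x, y2) by subject-level bootstrap.

    Each replicate draws n subject indices with replacement and computes
    the difference of the two Spearman correlations on the resampled rows.
    The percentile interval of the replicate deltas gives the CI; the
    two-sided p-value is ``2 * min(frac deltas <= 0, frac deltas >= 0)``
    clipped to [0, 1].  Replicates with an undefined correlation (a
    constant resampled vector) are redrawn, keeping the replicate count
    fixed; the redraw count is recorded.  Fully reproducible from ``seed``.
    """
    if seed is None:
        raise ValueError("bootstrap requires an explicit seed")
    if replicates < 100:
        raise ValueError("at least 100 replicates required")
    x = np.asarray(x, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if not (x.shape == y1.shape == y2.shape):
        raise ValueError("x, y1, y2 must share length")
    n = x.size
    if n < 5:
        raise ValueError(f"bootstrap requires n >= 5 subjects, got {n}")
    for name, v in (("y1", y1), ("y2", y2)):
        if np.unique(v).size < 2:
            raise UndefinedCorrelationError(f"{name} is constant")

    r1 = spearman_rho(x, y1)
    r2 = spearman_rho(x, y2)

    rng = np.random.default_rng(seed)
    deltas = np.empty(replicates)
    deltas.fill(np.nan)
    pending = np.arange(replicates)
    n_redrawn = 0
    # redraw loop: only rows whose resample yielded an undefined correlation
    for _ in range(1000):
        if pending.size == 0:
            break
        idx = rng.integers(0, n, size=(pending.size, n))
        rx = _rank_rows(x[idx])
        ry1 = _rank_rows(y1[idx])
        ry2 = _rank_rows(y2[idx])
        d = _row_corr(rx, ry1) - _row_corr(rx, ry2)
        deltas[pending] = d
        bad = pending[np.isnan(d)]
        n_redrawn += bad.size
        pending = bad
    else:
        raise RuntimeError("could not obtain defined correlations after many redraws")

    alpha = 1.0 - level
    lo, hi = np.quantile(deltas, [alpha / 2, 1 - alpha / 2])
    p = 2.0 * min(float((deltas <= 0).mean()), float((deltas >= 0).mean()))
    p = float(min(max(p, 0.0), 1.0))
    return BootstrapComparison(
        rho_1=r1.rho,
        rho_2=r2.rho,
        delta=r1.rho - r2.rho,
        ci=(float(lo), float(hi)),
        p_value=p,
        replicates=replicates,
        level=level,
        seed=int(seed),
        n=int(n),
        n_redrawn=int(n_redrawn),
    )


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str


def _has_tied_ranks(values: np.ndarray) -> bool:
    return np.unique(values).size < values.size


def _exact_signed_rank_p(nz: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p with mid-ranks for tied |differences|.

    Enumerates the null distribution of T+ (sum of ranks of positive
    differences over all 2^n equiprobable sign assignments) by dynamic
    programming on doubled ranks, so mid-ranks stay integral.
    """
    r = sps.rankdata(np.abs(nz))
    t_plus = float(r[nz > 0].sum())
    doubled = np.round(2 * r).astype(int)
    probs = np.zeros(int(doubled.sum()) + 1)
    probs[0] = 1.0
    for w in doubled:
        shifted = np.zeros_like(probs)
        shifted[w:] = probs[: probs.size - w]
        probs = 0.5 * probs + 0.5 * shifted
    obs = int(round(2 * t_plus))
    lo = float(probs[: obs + 1].sum())
    hi = float(probs[obs:].sum())
    return t_plus, min(1.0, 2.0 * min(lo, hi))


def wilcoxon_signed_rank(
    paired_a: Sequence[float], paired_b: Sequence[float]
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are discarded; the exact null distribution (computed
    with mid-ranks, so tied differences are handled) is used for <= 25
    nonzero differences, the normal approximation with tie and continuity
    correction otherwise.  All differences zero is degenerate: p = 1 with
    a warning.  The statistic is T+, the rank sum of positive differences.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must share length")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return TestResult(0.0, 1.0, "wilcoxon_signed_rank")
    if nz.size <= 25:
        stat, p = _exact_signed_rank_p(nz)
        return TestResult(stat, p, "wilcoxon_signed_rank")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.wilcoxon(
            nz, zero_method="wilcox", correction=True, method="approx",
            alternative="two-sided",
        )
    r = sps.rankdata(np.abs(nz))
    t_plus = float(r[nz > 0].sum())
    return TestResult(t_plus, float(res.pvalue), "wilcoxon_signed_rank")


def mann_whitney_u(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test of two independent groups.

    Exact p for small untied samples (n_a * n_b <= 400 and no ties across
    the pooled data); tie-corrected normal approximation with continuity
    correction otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    exact = a.size * b.size <= 400 and not _has_tied_ranks(pooled)
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic",
        use_continuity=not exact,
    )
    return TestResult(float(res.statistic), float(res.pvalue), "mann_whitney_u")


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Sums hypergeometric tables with probability <= the observed table.
    A zero margin is degenerate: p = 1 with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table entries must be nonnegative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table; p = 1", stacklevel=2)
        return TestResult(np.nan, 1.0, "fisher_exact")
    res = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(float(res.statistic), float(res.pvalue), "fisher_exact")
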