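"""Deviation-from-reference statistics, Kendall's W, and Bland-Altman.

Agreement of visual assessments with a reference is quantified three ways:

* **Deviation statistics** — each evaluation is compared with the subject's
  reference key (a clinically assessed score, or the pair of scores from
  two senior clinicians, in which case the *closest* key is used and
  equidistance is broken toward the lower key).  The pooled mean absolute
  deviation, its standard error, the distribution of signed deviations and
  the complete-agreement fraction summarise an evaluator's reliability.
* **Kendall's coefficient of concordance W** — chance-corrected agreement
  of m raters ranking n subjects, with the mid-rank ties correction:

      W = 12 S / (m^2 (n^3 - n) - m * sum_j T_j)

  where S is the sum of squared deviations of subject rank-sums from their
  mean and T_j = sum over tied groups of rater j of (t^3 - t).  Significance
  uses the chi-square approximation chi2 = m (n - 1) W on n - 1 df.
* **Bland-Altman limits of agreement** — paired differences against paired
  means, limits at mean +/- 1.96 SD (sample SD, ddof=1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ScoreMatrix

__all__ = [
    "ReferenceKey",
    "DeviationRecord",
    "DeviationSummary",
    "ConcordanceResult",
    "BlandAltmanResult",
    "signed_deviation",
    "deviation_records",
    "deviation_summary",
    "kendalls_w",
    "bland_altman",
]


@dataclass(frozen=True)
class ReferenceKey:
    """Per-subject reference score set (one score, or a two-clinician pair)."""

    subject_id: str
    key_scores: frozenset[int]

    def __post_init__(self) -> None:
        if not self.key_scores:
            raise ValueError(f"empty reference key for subject {self.subject_id!r}")
        if len(self.key_scores) > 2:
            raise ValueError(
                f"reference key holds at most 2 scores, got {sorted(self.key_scores)}"
            )
        for k in self.key_scores:
            if not 1 <= k <= 9:
                raise ValueError(f"key score {k} outside 1-9")

    @classmethod
    def single(cls, subject_id: str, score: int) -> "ReferenceKey":
        return cls(subject_id, frozenset([int(score)]))

    @classmethod
    def pair(cls, subject_id: str, a: int, b: int) -> "ReferenceKey":
        return cls(subject_id, frozenset([int(a), int(b)]))


@dataclass(frozen=True)
class DeviationRecord:
    """One evaluation's deviation from the subject's closest reference key."""

    subject_id: str
    rater_id: str
    signed_deviation: int
    abs_deviation: int


def signed_deviation(score: int, key: ReferenceKey) -> int:
    """Signed deviation of a score from the closest reference key.

    The nearest key score minimises |score - key|; when the score is
    equidistant from two distinct keys, the lower key is used.
    """
    if not 1 <= score <= 9:
        raise ValueError(f"score {score} outside 1-9")
    nearest = min(sorted(key.key_scores), key=lambda k: abs(score - k))
    return int(score) - int(nearest)


def deviation_records(
    matrix: ScoreMatrix,
    keys: Mapping[str, ReferenceKey],
    raters: Sequence[str] | None = None,
) -> list[DeviationRecord]:
    """Pooled deviation records over the selected raters (all by default)."""
    raters = list(raters) if raters is not None else matrix.raters
    unknown = [r for r in raters if r not in matrix.raters]
    if unknown:
        raise KeyError(f"unknown rater ids: {unknown}")
    frame = matrix.frame
    records = []
    for subject in matrix.subjects:
        if subject not in keys:
            raise KeyError(f"no reference key for subject {subject!r}")
        key = keys[subject]
        for rater in raters:
            v = frame.loc[subject, rater]
            if pd.isna(v):
                continue
            d = signed_deviation(int(v), key)
            records.append(DeviationRecord(subject, rater, d, abs(d)))
    return records


@dataclass
class DeviationSummary:
    """Summary of deviations pooled over evaluations.

    ``sem`` is the sample (ddof=1) standard deviation of the absolute
    deviations divided by sqrt(n); ``distribution`` maps each signed
    deviation to its fraction of evaluations.
    """

    mean_abs: float
    sem: float
    n: int
    distribution: dict[int, float]
    complete_agreement_fraction: float


def deviation_summary(
    matrix: ScoreMatrix,
    keys: Mapping[str, ReferenceKey],
    raters: Sequence[str] | None = None,
) -> DeviationSummary:
    """Pooled deviation summary over the selected raters' evaluations."""
    records = deviation_records(matrix, keys, raters)
    if not records:
        raise ValueError("no evaluations selected")
    return summarize_deviations(records)


def summarize_deviations(records: Sequence[DeviationRecord]) -> DeviationSummary:
    if not records:
        raise ValueError("no deviation records to summarise")
    abs_dev = np.array([r.abs_deviation for r in records], dtype=float)
    signed = [r.signed_deviation for r in records]
    n = len(records)
    sem = float(abs_dev.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    dist = {
        d: signed.count(d) / n for d in sorted(set(signed))
    }
    return DeviationSummary(
        mean_abs=float(abs_dev.mean()),
        sem=sem,
        n=n,
        distribution=dist,
        complete_agreement_fraction=dist.get(0, 0.0),
    )


@dataclass(frozen=True)
class ConcordanceResult:
    """Kendall's W with its chi-square test."""

    W: float
    chi_square: float
    df: int
    p_value: float
    n_subjects: int
    n_raters: int


def kendalls_w(matrix: ScoreMatrix) -> ConcordanceResult:
    """Ties-corrected Kendall's coefficient of concordance among raters.

    Subjects with any missing evaluation are dropped (listwise-complete
    submatrix).  Requires >= 2 raters and >= 3 complete subjects.  A fully
    tied matrix (every rater constant) makes the ties correction consume
    the whole denominator; that degenerate case raises.
    """
    frame = matrix.frame.dropna(axis=0, how="any")
    n, m = frame.shape
    if m < 2:
        raise ValueError("kendalls_w requires at least 2 raters")
    if n < 3:
        raise ValueError("kendalls_w requires at least 3 complete subjects")
    values = frame.to_numpy(dtype=float)
    ranks = sps.rankdata(values, axis=0)  # mid-ranks within each rater column
    rank_sums = ranks.sum(axis=1)
    S = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    T = 0.0
    for j in range(m):
        _, counts = np.unique(values[:, j], return_counts=True)
        T += float((counts**3 - counts).sum())
    denom = m**2 * (n**3 - n) - m * T
    if denom <= 0:
        raise ValueError(
            "degenerate input: ties correction consumes the denominator "
            "(every rater assigned a constant score)"
        )
    W = 12.0 * S / denom
    chi2 = m * (n - 1) * W
    df = n - 1
    p = float(sps.chi2.sf(chi2, df))
    return ConcordanceResult(W=W, chi_square=chi2, df=df, p_value=p, n_subjects=n, n_raters=m)


@dataclass
class BlandAltmanResult:
    """Bland-Altman agreement of two paired series (differences a - b)."""

    mean_difference: float
    sd_difference: float
    limits: tuple[float, float]
    points: pd.DataFrame  # columns: mean, difference (one row per subject)


def bland_altman(
    series_a: Sequence[float], series_b: Sequence[float]
) -> BlandAltmanResult:
    """Limits of agreement between two paired measurement series.

    Differences are ``a - b``; limits are mean +/- 1.96 sample SD.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must be paired (equal length)")
    if a.size < 2:
        raise ValueError("bland_altman requires at least 2 pairs")
    diff = a - b
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    limits = (mean_diff - 1.96 * sd, mean_diff + 1.96 * sd)
    points = pd.DataFrame({"mean": (a + b) / 2.0, "difference": diff})
    return BlandAltmanResult(mean_diff, sd, limits, points)
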