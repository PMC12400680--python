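"""Diagnostic categories on the 9-point BCS scale and misclassification shifts.

The 9-point body-condition scale partitions into four ordered diagnostic
categories: 1-3 underweight (UW), 4-5 ideal weight (IW), 6-7 overweight
(OW), 8-9 obese (OB).  A *shift* occurs when the reference score and an
evaluator's score fall on opposite sides of a diagnostic boundary:

* ``IW_vs_OWOB`` — crossings of the boundary between the at-or-below-ideal
  side (UW or IW) and the overweight-or-obese side (OW or OB), in either
  direction.
* ``IW_vs_OB``  — only moves between IW and OB proper (one side IW, the
  other OB); clinically the relevant error when ideal-weight cats are
  compared with obese cats.

The shift rate's denominator is all paired subjects in both modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Mapping, Sequence

import pandas as pd

from .consensus import VoteResult
from .io import ScoreMatrix

__all__ = [
    "DiagnosisCategory",
    "ShiftSummary",
    "ShiftTable",
    "BOUNDARY_MODES",
    "categorize",
    "shift_analysis",
    "cohort_shift_table",
]


class DiagnosisCategory(IntEnum):
    """Ordered diagnostic categories: UW < IW < OW < OB."""

    UW = 0  # underweight, BCS 1-3
    IW = 1  # ideal weight, BCS 4-5
    OW = 2  # overweight (not obese), BCS 6-7
    OB = 3  # obese, BCS 8-9


BOUNDARY_MODES = ("IW_vs_OWOB", "IW_vs_OB")


def categorize(score: int) -> DiagnosisCategory:
    """Map a BCS 1-9 onto its diagnostic category."""
    score = int(score)
    if not 1 <= score <= 9:
        raise ValueError(f"score {score} outside 1-9")
    if score <= 3:
        return DiagnosisCategory.UW
    if score <= 5:
        return DiagnosisCategory.IW
    if score <= 7:
        return DiagnosisCategory.OW
    return DiagnosisCategory.OB


@dataclass(frozen=True)
class ShiftSummary:
    """Diagnosis shifts of one evaluator against the reference."""

    evaluator_id: str
    n_subjects: int
    boundary_mode: str
    n_shift_up: int  # reference lower side -> evaluator higher side
    n_shift_down: int
    shift_rate: float
    unchanged_rate: float


def _is_shift(ref_cat: DiagnosisCategory, ev_cat: DiagnosisCategory, mode: str) -> int:
    """0 = no shift, +1 = shift up (toward heavier), -1 = shift down."""
    if mode == "IW_vs_OWOB":
        ref_high = ref_cat >= DiagnosisCategory.OW
        ev_high = ev_cat >= DiagnosisCategory.OW
        if ref_high == ev_high:
            return 0
        return 1 if ev_high else -1
    if mode == "IW_vs_OB":
        cats = (ref_cat, ev_cat)
        if cats == (DiagnosisCategory.IW, DiagnosisCategory.OB):
            return 1
        if cats == (DiagnosisCategory.OB, DiagnosisCategory.IW):
            return -1
        return 0
    raise ValueError(f"unknown boundary mode {mode!r}; use one of {BOUNDARY_MODES}")


def shift_analysis(
    reference: Sequence[int],
    evaluator: Sequence[int],
    boundary_mode: str,
    evaluator_id: str = "",
) -> ShiftSummary:
    """Count diagnosis shifts of paired evaluator scores vs reference scores."""
    reference = list(reference)
    evaluator = list(evaluator)
    if len(reference) != len(evaluator):
        raise ValueError("reference and evaluator score lists must be paired")
    if not reference:
        raise ValueError("no paired subjects")
    up = down = 0
    for ref, ev in zip(reference, evaluator):
        s = _is_shift(categorize(ref), categorize(ev), boundary_mode)
        if s > 0:
            up += 1
        elif s < 0:
            down += 1
    n = len(reference)
    rate = (up + down) / n
    return ShiftSummary(
        evaluator_id=evaluator_id,
        n_subjects=n,
        boundary_mode=boundary_mode,
        n_shift_up=up,
        n_shift_down=down,
        shift_rate=rate,
        unchanged_rate=1.0 - rate,
    )


@dataclass
class ShiftTable:
    """Per-evaluator shift summaries plus the across-evaluator average.

    ``average_rate`` is the unweighted mean of the *individual raters'*
    shift rates; the majority-vote row (and any duplicated OCS row) is
    excluded from the average.
    """

    summaries: list[ShiftSummary]
    average_rate: float
    boundary_mode: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "evaluator": s.evaluator_id,
                    "mode": s.boundary_mode,
                    "n_subjects": s.n_subjects,
                    "n_shift_up": s.n_shift_up,
                    "n_shift_down": s.n_shift_down,
                    "shift_rate": s.shift_rate,
                    "unchanged_rate": s.unchanged_rate,
                }
                for s in self.summaries
            ]
        )


def cohort_shift_table(
    reference: Mapping[str, int],
    matrix: ScoreMatrix,
    votes: Mapping[str, VoteResult] | None,
    boundary_mode: str,
    ocs_rater: str | None = None,
) -> ShiftTable:
    """Shift summaries for every rater, the majority vote, and the OCS.

    ``reference`` maps subject id -> reference score and must cover all
    matrix subjects.  Missing evaluations are dropped pairwise.  The
    across-evaluator average is over the individual raters only.
    """
    for s in matrix.subjects:
        if s not in reference:
            raise KeyError(f"reference does not cover subject {s!r}")
    frame = matrix.frame
    summaries: list[ShiftSummary] = []
    rater_rates: list[float] = []
    for rater in matrix.raters:
        col = frame[rater]
        subjects = [s for s in matrix.subjects if pd.notna(col.loc[s])]
        summary = shift_analysis(
            [int(reference[s]) for s in subjects],
            [int(col.loc[s]) for s in subjects],
            boundary_mode,
            evaluator_id=rater,
        )
        summaries.append(summary)
        rater_rates.append(summary.shift_rate)
    if votes is not None:
        subjects = [s for s in matrix.subjects if s in votes]
        summaries.append(
            shift_analysis(
                [int(reference[s]) for s in subjects],
                [votes[s].vote for s in subjects],
                boundary_mode,
                evaluator_id="MV",
            )
        )
    if ocs_rater is not None:
        if ocs_rater not in matrix.raters:
            raise KeyError(f"OCS rater {ocs_rater!r} not in matrix")
        col = frame[ocs_rater]
        subjects = [s for s in matrix.subjects if pd.notna(col.loc[s])]
        summaries.append(
            shift_analysis(
                [int(reference[s]) for s in subjects],
                [int(col.loc[s]) for s in subjects],
                boundary_mode,
                evaluator_id="OCS",
            )
        )
    return ShiftTable(
        summaries=summaries,
        average_rate=sum(rater_rates) / len(rater_rates),
        boundary_mode=boundary_mode,
    )
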