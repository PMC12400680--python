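"""Majority-vote consensus of rater scores and duplicate-pair integrity.

The consensus score of a subject is the most frequent score among its
raters (the "majority vote", MV).  When several scores tie for the highest
count, the tie is resolved using the remaining (non-candidate) scores:

1. choose the tied candidate with the smallest mean absolute distance to
   the multiset of remaining scores;
2. if no scores remain or step 1 still ties, choose the candidate closest
   to the median of *all* scores;
3. if still tied, choose the lower score (conservative: biases against
   over-diagnosis).

The chain uses only multisets, so the vote is invariant to any permutation
of the input scores, and always lies within [min(scores), max(scores)].
Confidence annotations never enter the tally; the vote is defined on
primary scores only.
"""

from __future__ import annotations

import statistics
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .io import DuplicateRegistry, ScoreMatrix

__all__ = [
    "VoteResult",
    "DuplicatePairReport",
    "majority_vote",
    "consensus_scores",
    "duplicate_consistency",
]


@dataclass(frozen=True)
class VoteResult:
    """Consensus score for one subject with tie metadata."""

    subject_id: str
    vote: int
    tally: dict[int, int]
    tie_broken: bool
    tie_candidates: frozenset[int]


def majority_vote(scores: list[int], subject_id: str = "") -> VoteResult:
    """Majority vote over a non-empty list of ordinal scores (1-9).

    Missing entries must already be removed.  Deterministic and invariant
    to permutation of the input.
    """
    if not scores:
        raise ValueError(f"majority_vote: empty score list (subject {subject_id!r})")
    for s in scores:
        if not 1 <= int(s) <= 9:
            raise ValueError(f"score {s} outside 1-9 (subject {subject_id!r})")
    scores = [int(s) for s in scores]
    tally = Counter(scores)
    top = max(tally.values())
    candidates = sorted(s for s, c in tally.items() if c == top)
    if len(candidates) == 1:
        return VoteResult(subject_id, candidates[0], dict(tally), False, frozenset(candidates))

    remaining = [s for s in scores if s not in candidates]
    pool = candidates
    if remaining:
        dist = {c: sum(abs(c - r) for r in remaining) / len(remaining) for c in pool}
        best = min(dist.values())
        pool = [c for c in pool if dist[c] == best]
    if len(pool) > 1:
        med = statistics.median(scores)
        dist2 = {c: abs(c - med) for c in pool}
        best2 = min(dist2.values())
        pool = [c for c in pool if dist2[c] == best2]
    vote = min(pool)  # lower-score fallback
    return VoteResult(subject_id, vote, dict(tally), True, frozenset(candidates))


def consensus_scores(matrix: ScoreMatrix) -> dict[str, VoteResult]:
    """Per-subject majority vote, ordered by the matrix's subject order.

    Raises if any subject has no non-missing score.
    """
    out: dict[str, VoteResult] = {}
    for subject in matrix.subjects:
        row = list(matrix.row(subject).values())
        if not row:
            raise ValueError(f"subject {subject!r} has no non-missing scores")
        out[subject] = majority_vote(row, subject)
    return out


@dataclass
class DuplicatePairReport:
    """Scoring consistency for one duplicated subject pair.

    Differences are *second minus first* pair member; ``rater_diffs`` holds
    None where either evaluation is missing.
    """

    pair: tuple[str, str]
    rater_diffs: dict[str, int | None]
    vote_diff: int
    votes: tuple[int, int]
    abs_diff_distribution: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.abs_diff_distribution:
            counts = Counter(
                abs(d) for d in self.rater_diffs.values() if d is not None
            )
            self.abs_diff_distribution = dict(sorted(counts.items()))


def duplicate_consistency(
    matrix: ScoreMatrix,
    registry: DuplicateRegistry,
    votes: dict[str, VoteResult] | None = None,
) -> list[DuplicatePairReport]:
    """Per-pair signed rater differences and vote differences.

    The two members of each registry pair are altered presentations of the
    same animal, so systematic differences expose presentation effects
    (pose, angle) rather than true condition changes.
    """
    present = set(matrix.subjects)
    for member in registry.members:
        if member not in present:
            raise KeyError(f"registry subject {member!r} not present in score matrix")
    if votes is None:
        votes = consensus_scores(matrix)
    frame = matrix.frame
    reports = []
    for a, b in registry.pairs:
        diffs: dict[str, int | None] = {}
        for r in matrix.raters:
            va, vb = frame.loc[a, r], frame.loc[b, r]
            diffs[r] = None if (pd.isna(va) or pd.isna(vb)) else int(vb) - int(va)
        reports.append(
            DuplicatePairReport(
                pair=(a, b),
                rater_diffs=diffs,
                vote_diff=votes[b].vote - votes[a].vote,
                votes=(votes[a].vote, votes[b].vote),
            )
        )
    return reports
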