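"""Data model and CSV readers/writers for rater score tables.

A scoring study is held in four small containers:

* :class:`ScoreMatrix` — subjects x raters table of ordinal body-condition
  scores (BCS, 1-9), missing entries allowed.  Every statistic in the
  package consumes this object.
* :class:`CohortTable` — per-subject metadata: body weight (kg), the
  clinically assessed BCS (CA-BCS) and free-form attributes.
* :class:`DuplicateRegistry` — pairs of subject ids that are altered
  duplicates of the same animal, used for scoring-consistency checks.
* :class:`ScoreRecord` — one rater's judgment for one subject, optionally
  carrying a confidence annotation (levels A/B/C, see
  :func:`parse_confidence_notation`).

CSV dialects
------------
``long``  columns ``subject,rater,score[,confidence_raw]``; one row per
          (subject, rater) evaluation.
``wide``  columns ``subject,<rater_1>,...,<rater_k>``; one row per subject.

Score cells may contain confidence notation (``"5"``, ``"5 = 6"``,
``"5 > 6"``); the first-listed (primary) score is used as the matrix value.
Missing evaluations are empty fields.  All output is UTF-8 with
deterministic row order (file order of subjects and raters).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ScoreRecord",
    "ParsedScore",
    "ScoreMatrix",
    "CohortTable",
    "DuplicateRegistry",
    "ScoreParseError",
    "ValidationFinding",
    "ValidationReport",
    "parse_confidence_notation",
    "read_score_table",
    "write_score_table",
    "read_cohort_table",
    "write_cohort_table",
    "read_duplicate_registry",
    "write_duplicate_registry",
    "validate_score_matrix",
]

SCORE_MIN, SCORE_MAX = 1, 9


class ScoreParseError(ValueError):
    """A score cell or confidence annotation could not be parsed."""


def _check_score_range(value: int, token: str) -> int:
    if not SCORE_MIN <= value <= SCORE_MAX:
        raise ScoreParseError(
            f"score {value!r} outside valid range {SCORE_MIN}-{SCORE_MAX} "
            f"in token {token!r}"
        )
    return value


@dataclass(frozen=True)
class ParsedScore:
    """Primary/secondary score plus confidence level from one raw cell."""

    primary: int
    secondary: int | None = None
    confidence: str | None = None  # 'A', 'B' or 'C'


_SINGLE = re.compile(r"^\s*(\d+)\s*$")
_PAIR = re.compile(r"^\s*(\d+)\s*([=>])\s*(\d+)\s*$")


def parse_confidence_notation(raw: str) -> ParsedScore:
    """Parse a score cell in the study's confidence notation.

    Three grammars are accepted:

    * ``"n"``       — plain score, no confidence recorded.
    * ``"n = n"``   — level A: the evaluator is fully confident in a single
      score (the two listed scores are equal).
    * ``"n = m"``   — level B: two *adjacent* scores considered equally
      likely; the first-listed score is the primary.
    * ``"n > m"``   — level C: two adjacent scores with a lean toward the
      first-listed one.

    Raises
    ------
    ScoreParseError
        For malformed text, scores outside 1-9, or a non-adjacent pair
        under level B/C.
    """
    if not isinstance(raw, str):
        raise ScoreParseError(f"expected text score cell, got {raw!r}")
    m = _SINGLE.match(raw)
    if m:
        return ParsedScore(_check_score_range(int(m.group(1)), raw))
    m = _PAIR.match(raw)
    if m is None:
        raise ScoreParseError(f"unrecognised score notation {raw!r}")
    first = _check_score_range(int(m.group(1)), raw)
    second = _check_score_range(int(m.group(3)), raw)
    op = m.group(2)
    if op == "=" and first == second:
        return ParsedScore(first, None, "A")
    if abs(second - first) != 1:
        raise ScoreParseError(
            f"non-adjacent score pair {first} and {second} in {raw!r}: "
            "levels B/C admit adjacent scores only"
        )
    return ParsedScore(first, second, "B" if op == "=" else "C")


@dataclass(frozen=True)
class ScoreRecord:
    """One rater's judgment of one subject with optional confidence."""

    subject_id: str
    rater_id: str
    primary_score: int
    secondary_score: int | None = None
    confidence: str | None = None

    def __post_init__(self) -> None:
        _check_score_range(self.primary_score, str(self.primary_score))
        if self.secondary_score is not None:
            _check_score_range(self.secondary_score, str(self.secondary_score))
            if abs(self.secondary_score - self.primary_score) != 1:
                raise ValueError(
                    "secondary score must be adjacent to primary "
                    f"({self.primary_score} vs {self.secondary_score})"
                )
        if self.confidence is not None and self.confidence not in ("A", "B", "C"):
            raise ValueError(f"confidence must be A, B or C, got {self.confidence!r}")
        if self.confidence == "A" and self.secondary_score is not None:
            raise ValueError("confidence A records carry no distinct secondary score")
        if self.confidence in ("B", "C") and self.secondary_score is None:
            raise ValueError(f"confidence {self.confidence} requires a secondary score")


class ScoreMatrix:
    """Subjects x raters table of ordinal scores with missing entries.

    Parameters
    ----------
    frame
        DataFrame indexed by subject id with one column per rater id.
        Values are integers 1-9 or missing (NA).
    validate
        When True (default), reject duplicate ids and out-of-range scores.
    """

    def __init__(self, frame: pd.DataFrame, *, validate: bool = True) -> None:
        frame = frame.copy()
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        frame = frame.astype("Float64").astype("Int64")
        if validate:
            if frame.index.has_duplicates:
                dupes = frame.index[frame.index.duplicated()].tolist()
                raise ValueError(f"duplicate subject ids: {dupes}")
            if frame.columns.has_duplicates:
                dupes = frame.columns[frame.columns.duplicated()].tolist()
                raise ValueError(f"duplicate rater ids: {dupes}")
            bad = frame.notna() & ((frame < SCORE_MIN) | (frame > SCORE_MAX))
            if bad.any().any():
                cells = [
                    (frame.index[int(i)], frame.columns[int(j)])
                    for i, j in zip(*bad.values.nonzero())
                ]
                raise ValueError(f"scores outside {SCORE_MIN}-{SCORE_MAX} at cells {cells}")
        self._frame = frame

    @classmethod
    def from_records(cls, records: Iterable[ScoreRecord]) -> "ScoreMatrix":
        """Build a matrix from records; subject/rater order is first appearance."""
        subjects: list[str] = []
        raters: list[str] = []
        cells: dict[tuple[str, str], int] = {}
        for rec in records:
            key = (rec.subject_id, rec.rater_id)
            if key in cells:
                raise ValueError(f"duplicate (subject, rater) pair {key}")
            cells[key] = rec.primary_score
            if rec.subject_id not in subjects:
                subjects.append(rec.subject_id)
            if rec.rater_id not in raters:
                raters.append(rec.rater_id)
        frame = pd.DataFrame(index=subjects, columns=raters, dtype="Float64")
        for (s, r), v in cells.items():
            frame.loc[s, r] = v
        return cls(frame)

    @classmethod
    def from_dict(
        cls,
        scores: Mapping[str, Sequence[int | None]],
        subjects: Sequence[str] | None = None,
    ) -> "ScoreMatrix":
        """Build from a mapping rater id -> per-subject score list."""
        frame = pd.DataFrame(dict(scores), dtype="Float64")
        if subjects is not None:
            frame.index = list(subjects)
        else:
            frame.index = [str(i + 1) for i in range(len(frame))]
        return cls(frame)

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying nullable-integer DataFrame (a copy)."""
        return self._frame.copy()

    @property
    def subjects(self) -> list[str]:
        return list(self._frame.index)

    @property
    def raters(self) -> list[str]:
        return list(self._frame.columns)

    @property
    def n_subjects(self) -> int:
        return len(self._frame.index)

    @property
    def n_raters(self) -> int:
        return len(self._frame.columns)

    def row(self, subject_id: str) -> dict[str, int]:
        """Non-missing scores for one subject, keyed by rater id."""
        r = self._frame.loc[subject_id]
        return {k: int(v) for k, v in r.items() if pd.notna(v)}

    def column(self, rater_id: str) -> pd.Series:
        return self._frame[rater_id]

    def select_raters(self, raters: Sequence[str]) -> "ScoreMatrix":
        missing = [r for r in raters if r not in self._frame.columns]
        if missing:
            raise KeyError(f"unknown rater ids: {missing}")
        return ScoreMatrix(self._frame[list(raters)], validate=False)

    def select_subjects(self, subjects: Sequence[str]) -> "ScoreMatrix":
        missing = [s for s in subjects if s not in self._frame.index]
        if missing:
            raise KeyError(f"unknown subject ids: {missing}")
        return ScoreMatrix(self._frame.loc[list(subjects)], validate=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScoreMatrix):
            return NotImplemented
        return self._frame.equals(other._frame)

    def __repr__(self) -> str:
        return f"ScoreMatrix({self.n_subjects} subjects x {self.n_raters} raters)"


@dataclass
class CohortTable:
    """Per-subject metadata: body weight (kg), CA-BCS, free attributes.

    ``table`` is indexed by subject id; recognised columns are
    ``body_weight_kg`` (float > 0 or NA) and ``ca_bcs`` (integer 1-9 or NA);
    any further columns are carried as free metadata.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        t.index = t.index.astype(str)
        if "body_weight_kg" in t.columns:
            t["body_weight_kg"] = pd.to_numeric(t["body_weight_kg"], errors="raise")
            w = t["body_weight_kg"]
            if (w.dropna() <= 0).any():
                bad = t.index[w.notna() & (w <= 0)].tolist()
                raise ValueError(f"non-positive body weight for subjects {bad}")
        if "ca_bcs" in t.columns:
            t["ca_bcs"] = pd.to_numeric(t["ca_bcs"], errors="raise").astype("Int64")
            c = t["ca_bcs"].dropna()
            if ((c < SCORE_MIN) | (c > SCORE_MAX)).any():
                raise ValueError("ca_bcs outside 1-9")
        self.table = t

    @property
    def subjects(self) -> list[str]:
        return list(self.table.index)

    def ca_bcs(self) -> pd.Series:
        if "ca_bcs" not in self.table.columns:
            raise KeyError("cohort table has no ca_bcs column")
        return self.table["ca_bcs"]

    def body_weight(self) -> pd.Series:
        if "body_weight_kg" not in self.table.columns:
            raise KeyError("cohort table has no body_weight_kg column")
        return self.table["body_weight_kg"]


@dataclass(frozen=True)
class DuplicateRegistry:
    """Pairs of subject ids that are altered duplicates of one animal."""

    pairs: tuple[tuple[str, str], ...]

    def __init__(self, pairs: Iterable[tuple[str, str]]) -> None:
        norm = tuple((str(a), str(b)) for a, b in pairs)
        seen: set[str] = set()
        for a, b in norm:
            if a == b:
                raise ValueError(f"duplicate pair members must differ ({a!r})")
            for x in (a, b):
                if x in seen:
                    raise ValueError(f"subject {x!r} appears in more than one pair")
                seen.add(x)
        object.__setattr__(self, "pairs", norm)

    @property
    def members(self) -> set[str]:
        return {x for pair in self.pairs for x in pair}

    @property
    def second_members(self) -> list[str]:
        """Ids of the injected duplicates (second member of each pair)."""
        return [b for _, b in self.pairs]


# ---------------------------------------------------------------------------
# CSV I/O

_LONG_COLS = ["subject", "rater", "score"]


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def read_score_table(path: str | Path, dialect: str = "long") -> ScoreMatrix:
    """Read a rater score table from CSV.

    Confidence notation in score cells is parsed with
    :func:`parse_confidence_notation`; the primary score becomes the matrix
    value.  Empty cells are missing evaluations.
    """
    if dialect not in ("long", "wide"):
        raise ValueError(f"dialect must be 'long' or 'wide', got {dialect!r}")
    df = _read_csv(path)
    if dialect == "long":
        missing_cols = [c for c in _LONG_COLS if c not in df.columns]
        if missing_cols:
            raise ScoreParseError(
                f"{path}: long dialect requires header columns {_LONG_COLS}, "
                f"missing {missing_cols}"
            )
        subjects: list[str] = []
        raters: list[str] = []
        cells: dict[tuple[str, str], int | None] = {}
        for i, row in df.iterrows():
            s, r, raw = row["subject"], row["rater"], row["score"]
            key = (s, r)
            if key in cells:
                raise ScoreParseError(f"{path} row {i + 2}: duplicate (subject, rater) {key}")
            if raw.strip() == "":
                cells[key] = None
            else:
                try:
                    cells[key] = parse_confidence_notation(raw).primary
                except ScoreParseError as e:
                    raise ScoreParseError(f"{path} row {i + 2}, column 'score': {e}") from e
            if s not in subjects:
                subjects.append(s)
            if r not in raters:
                raters.append(r)
        frame = pd.DataFrame(index=subjects, columns=raters, dtype="Float64")
        for (s, r), v in cells.items():
            if v is not None:
                frame.loc[s, r] = v
        return ScoreMatrix(frame)
    # wide
    if df.columns[0] != "subject":
        raise ScoreParseError(f"{path}: wide dialect requires first column 'subject'")
    raters = [c for c in df.columns[1:]]
    subjects = df["subject"].tolist()
    frame = pd.DataFrame(index=subjects, columns=raters, dtype="Float64")
    for i, row in df.iterrows():
        for r in raters:
            raw = row[r]
            if raw.strip() == "":
                continue
            try:
                frame.loc[row["subject"], r] = parse_confidence_notation(raw).primary
            except ScoreParseError as e:
                raise ScoreParseError(f"{path} row {i + 2}, column {r!r}: {e}") from e
    return ScoreMatrix(frame)


def write_score_table(matrix: ScoreMatrix, path: str | Path, dialect: str = "long") -> None:
    """Write a score matrix to CSV; missing cells become empty fields.

    Round-trip property: ``read_score_table(write(m)) == m`` for both
    dialects (for matrices with at least one subject).
    """
    if dialect not in ("long", "wide"):
        raise ValueError(f"dialect must be 'long' or 'wide', got {dialect!r}")
    frame = matrix.frame
    path = Path(path)
    if dialect == "long":
        rows = []
        for s in matrix.subjects:
            for r in matrix.raters:
                v = frame.loc[s, r]
                rows.append(
                    {"subject": s, "rater": r, "score": "" if pd.isna(v) else str(int(v))}
                )
        out = pd.DataFrame(rows, columns=_LONG_COLS)
        out.to_csv(path, index=False, encoding="utf-8")
    else:
        out = frame.astype(object).where(frame.notna(), "")
        out = out.map(lambda v: "" if v == "" else str(int(v)))
        out.index.name = "subject"
        out.to_csv(path, encoding="utf-8")


def read_cohort_table(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, dtype={"subject": str})
    if "subject" not in df.columns:
        raise ScoreParseError(f"{path}: cohort table requires a 'subject' column")
    df = df.set_index("subject")
    return CohortTable(df)


def write_cohort_table(cohort: CohortTable, path: str | Path) -> None:
    out = cohort.table.copy()
    out.index.name = "subject"
    out.to_csv(path, encoding="utf-8")


def read_duplicate_registry(path: str | Path) -> DuplicateRegistry:
    df = _read_csv(path)
    for col in ("subject_a", "subject_b"):
        if col not in df.columns:
            raise ScoreParseError(f"{path}: registry requires columns subject_a,subject_b")
    return DuplicateRegistry(list(zip(df["subject_a"], df["subject_b"])))


def write_duplicate_registry(registry: DuplicateRegistry, path: str | Path) -> None:
    pd.DataFrame(registry.pairs, columns=["subject_a", "subject_b"]).to_csv(
        path, index=False, encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# Validation


@dataclass(frozen=True)
class ValidationFinding:
    """One problem found during validation."""

    code: str  # 'range', 'missing_in_cohort', 'registry_unknown', ...
    location: str
    message: str


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_score_matrix`.

    ``findings`` is empty iff all checks pass; ``missing_per_rater`` carries
    informational per-rater missingness counts.
    """

    findings: list[ValidationFinding] = field(default_factory=list)
    missing_per_rater: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.findings

    def __bool__(self) -> bool:  # truthy == clean
        return self.ok

    def __str__(self) -> str:
        if self.ok:
            return "validation: OK"
        lines = [f"validation: {len(self.findings)} finding(s)"]
        lines += [f"  [{f.code}] {f.location}: {f.message}" for f in self.findings]
        return "\n".join(lines)


def validate_score_matrix(
    matrix: ScoreMatrix,
    cohort: CohortTable | None = None,
    registry: DuplicateRegistry | None = None,
) -> ValidationReport:
    """Check a score matrix (and optional companions) for consistency.

    Reports score-range violations, matrix subjects absent from the cohort
    table, registry ids absent from the matrix, and per-rater missingness
    counts.  Purely reporting: inputs are never mutated.
    """
    report = ValidationReport()
    frame = matrix.frame
    bad = frame.notna() & ((frame < SCORE_MIN) | (frame > SCORE_MAX))
    for i, j in zip(*bad.values.nonzero()):
        s, r = frame.index[int(i)], frame.columns[int(j)]
        report.findings.append(
            ValidationFinding(
                "range", f"({s}, {r})", f"score {int(frame.loc[s, r])} outside 1-9"
            )
        )
    if cohort is not None:
        known = set(cohort.subjects)
        for s in matrix.subjects:
            if s not in known:
                report.findings.append(
                    ValidationFinding(
                        "missing_in_cohort", s, "subject absent from cohort table"
                    )
                )
    if registry is not None:
        present = set(matrix.subjects)
        for member in sorted(registry.members):
            if member not in present:
                report.findings.append(
                    ValidationFinding(
                        "registry_unknown", member, "registry id absent from score matrix"
                    )
                )
    report.missing_per_rater = {
        r: int(frame[r].isna().sum()) for r in matrix.raters
    }
    return report
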