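"""Model/Results interface for the multi-rater agreement analysis.

:class:`RaterAgreementModel` is built from a score matrix plus a reference
specification and optional cohort metadata; :meth:`RaterAgreementModel.fit`
runs the whole analysis and returns an :class:`AgreementResults` carrying

* per-evaluator deviation statistics (mean absolute deviation, SEM,
  complete-agreement fraction) including the majority-vote row, with a
  paired Wilcoxon comparison of each evaluator against the vote;
* ties-corrected Kendall's W with its chi-square test;
* a Bland-Altman comparison of the mean evaluated score against the
  reference;
* the full Spearman correlation matrix (raters, vote, OCS, clinical score,
  body weight) and optional bootstrap comparisons of dependent overlapping
  correlations;
* diagnostic-category shift tables at both clinically relevant boundaries;
* duplicate-pair consistency reports.

Reference modes
---------------
``"ca_bcs"``
    the clinically assessed score from the cohort table is the per-subject
    reference (the validation-cohort design).
``("dual", rater_a, rater_b)``
    the two named raters' scores form a two-score key; the *closest* key is
    used for deviations and the remaining raters are the evaluated set (the
    internet-image design with two senior clinicians as the answer key).
A mapping ``subject -> ReferenceKey`` may also be given directly.

When a duplicate registry is present and the reference is per-animal
(``ca_bcs``), the injected duplicate presentations are excluded from the
deviation/correlation/shift pools (each animal contributes once) and are
analysed separately in the duplicate-pair report; concordance (W) is
computed on the full presented matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    BlandAltmanResult,
    ConcordanceResult,
    DeviationSummary,
    ReferenceKey,
    bland_altman,
    deviation_records,
    kendalls_w,
    signed_deviation,
    summarize_deviations,
)
from .consensus import DuplicatePairReport, VoteResult, consensus_scores, duplicate_consistency
from .diagnosis import BOUNDARY_MODES, ShiftTable, cohort_shift_table
from .io import (
    CohortTable,
    DuplicateRegistry,
    ScoreMatrix,
    read_cohort_table,
    read_duplicate_registry,
    read_score_table,
    validate_score_matrix,
)
from .stats import (
    BootstrapComparison,
    CorrelationMatrixResult,
    bootstrap_dependent_rho_diff,
    correlation_matrix,
    wilcoxon_signed_rank,
)

__all__ = ["RaterAgreementModel", "AgreementResults"]


class RaterAgreementModel:
    """Multi-rater ordinal-score agreement model.

    Parameters
    ----------
    matrix
        Subjects x raters score table.
    reference
        ``"ca_bcs"``, ``("dual", rater_a, rater_b)``, or a mapping
        ``subject -> ReferenceKey``.
    cohort
        Per-subject metadata (required for the ``ca_bcs`` reference and for
        body-weight correlations).
    registry
        Duplicate-pair registry; enables the consistency report and (for
        per-animal references) de-duplication of the analysis pools.
    ocs_rater
        Id of the rater who produced the clinical reference scores (the
        "original clinical scorer"); adds OCS rows/columns.
    dedup
        Exclude duplicate second-members from deviation/correlation/shift
        pools.  Default: automatic (True iff reference is ``ca_bcs`` and a
        registry is present).
    """

    def __init__(
        self,
        matrix: ScoreMatrix,
        reference: str | tuple | Mapping[str, ReferenceKey] = "ca_bcs",
        *,
        cohort: CohortTable | None = None,
        registry: DuplicateRegistry | None = None,
        ocs_rater: str | None = None,
        dedup: bool | None = None,
    ) -> None:
        self.matrix = matrix
        self.cohort = cohort
        self.registry = registry
        self.ocs_rater = ocs_rater
        self.reference_spec = reference
        if ocs_rater is not None and ocs_rater not in matrix.raters:
            raise KeyError(f"OCS rater {ocs_rater!r} not in matrix")

        if isinstance(reference, str):
            if reference != "ca_bcs":
                raise ValueError(f"unknown reference mode {reference!r}")
            if cohort is None:
                raise ValueError("ca_bcs reference requires a cohort table")
            ca = cohort.ca_bcs()
            self.keys = {}
            for s in matrix.subjects:
                if s not in ca.index or pd.isna(ca.loc[s]):
                    raise ValueError(f"no CA-BCS available for subject {s!r}")
                self.keys[s] = ReferenceKey.single(s, int(ca.loc[s]))
            self.key_raters: tuple[str, ...] = ()
            self.mode = "ca_bcs"
        elif isinstance(reference, tuple) and reference and reference[0] == "dual":
            _, ra, rb = reference
            for r in (ra, rb):
                if r not in matrix.raters:
                    raise KeyError(f"key rater {r!r} not in matrix")
            frame = matrix.frame
            self.keys = {}
            for s in matrix.subjects:
                va, vb = frame.loc[s, ra], frame.loc[s, rb]
                if pd.isna(va) or pd.isna(vb):
                    raise ValueError(f"key raters missing a score for subject {s!r}")
                self.keys[s] = ReferenceKey(s, frozenset([int(va), int(vb)]))
            self.key_raters = (ra, rb)
            self.mode = "dual"
        elif isinstance(reference, Mapping):
            self.keys = {s: reference[s] for s in matrix.subjects}
            self.key_raters = ()
            self.mode = "explicit"
        else:
            raise ValueError(f"unrecognised reference specification {reference!r}")

        if dedup is None:
            dedup = self.mode == "ca_bcs" and registry is not None
        self.dedup = bool(dedup)

    @classmethod
    def from_csv(
        cls,
        scores_path: str | Path,
        *,
        dialect: str = "long",
        cohort_path: str | Path | None = None,
        registry_path: str | Path | None = None,
        reference: str | tuple = "ca_bcs",
        ocs_rater: str | None = None,
        dedup: bool | None = None,
    ) -> "RaterAgreementModel":
        """Build a model straight from the CSV interchange files."""
        matrix = read_score_table(scores_path, dialect=dialect)
        cohort = read_cohort_table(cohort_path) if cohort_path else None
        registry = read_duplicate_registry(registry_path) if registry_path else None
        return cls(
            matrix,
            reference,
            cohort=cohort,
            registry=registry,
            ocs_rater=ocs_rater,
            dedup=dedup,
        )

    # -- helpers ----------------------------------------------------------

    @property
    def evaluated_raters(self) -> list[str]:
        """Raters whose deviations are scored (key raters excluded)."""
        return [r for r in self.matrix.raters if r not in self.key_raters]

    @property
    def analysis_subjects(self) -> list[str]:
        """Subjects entering deviation/correlation/shift pools."""
        if self.dedup and self.registry is not None:
            drop = set(self.registry.second_members)
            return [s for s in self.matrix.subjects if s not in drop]
        return list(self.matrix.subjects)

    def validate(self):
        return validate_score_matrix(self.matrix, self.cohort, self.registry)

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        *,
        bootstrap_replicates: int = 0,
        bootstrap_level: float = 0.95,
        bootstrap_comparisons: Sequence[tuple[str, str, str]] | None = None,
        seed: int | None = None,
    ) -> "AgreementResults":
        """Run the full agreement analysis.

        ``bootstrap_replicates > 0`` enables the dependent-correlation
        bootstrap comparisons (a seed is then mandatory);
        ``bootstrap_comparisons`` lists ``(shared_x, y1, y2)`` column names
        from the assembled correlation columns, defaulting to the vote-vs-
        OCS and clinical-vs-vote contrasts when those columns exist.
        """
        matrix = self.matrix
        votes = consensus_scores(matrix)
        subjects = self.analysis_subjects
        sub = matrix.select_subjects(subjects)
        keys = {s: self.keys[s] for s in subjects}

        # deviation table -------------------------------------------------
        rows = []
        per_rater_records: dict[str, dict[str, int]] = {}
        pooled_records = []
        for rater in self.evaluated_raters:
            recs = deviation_records(sub, keys, [rater])
            per_rater_records[rater] = {r.subject_id: r.abs_deviation for r in recs}
            pooled_records.extend(recs)
            rows.append(("Scorer " + rater, rater, summarize_deviations(recs)))
        vote_abs = {
            s: abs(signed_deviation(votes[s].vote, keys[s])) for s in subjects
        }
        vote_summary = summarize_deviations(
            [_vote_record(s, votes[s].vote, keys[s]) for s in subjects]
        )
        rows.append(("Vote", "MV", vote_summary))
        if self.ocs_rater is not None and self.ocs_rater in self.evaluated_raters:
            rows.append(
                (
                    "OCS",
                    self.ocs_rater,
                    summarize_deviations(deviation_records(sub, keys, [self.ocs_rater])),
                )
            )

        table_rows = []
        for label, rater, summary in rows:
            if rater == "MV":
                p_vs_vote = np.nan
            else:
                common = [s for s in subjects if s in per_rater_records[rater]]
                p_vs_vote = wilcoxon_signed_rank(
                    [per_rater_records[rater][s] for s in common],
                    [vote_abs[s] for s in common],
                ).p_value
            table_rows.append(
                {
                    "evaluator": label,
                    "n": summary.n,
                    "mean_abs_deviation": summary.mean_abs,
                    "sem": summary.sem,
                    "complete_agreement": summary.complete_agreement_fraction,
                    "p_vs_vote": p_vs_vote,
                }
            )
        deviation_table = pd.DataFrame(table_rows).set_index("evaluator")
        pooled = summarize_deviations(pooled_records)

        # concordance on the full presented matrix ------------------------
        concordance = kendalls_w(matrix)

        # Bland-Altman: mean evaluated score vs (closest) reference -------
        frame = sub.frame
        mean_scores = frame[self.evaluated_raters].astype(float).mean(axis=1)
        ref_vals = []
        for s in subjects:
            ks = sorted(keys[s].key_scores)
            ref_vals.append(min(ks, key=lambda k: abs(mean_scores.loc[s] - k)))
        ba = bland_altman(mean_scores.to_numpy(), np.array(ref_vals, dtype=float))

        # correlation matrix ----------------------------------------------
        cols: dict[str, pd.Series] = {}
        for rater in matrix.raters:
            cols[f"Scorer {rater}"] = frame[rater].astype(float)
        cols["MV"] = pd.Series({s: float(votes[s].vote) for s in subjects})
        if self.ocs_rater is not None:
            cols["OCS"] = frame[self.ocs_rater].astype(float)
        if self.cohort is not None and "ca_bcs" in self.cohort.table.columns:
            cols["CA-BCS"] = self.cohort.ca_bcs().reindex(subjects).astype(float)
        if self.cohort is not None and "body_weight_kg" in self.cohort.table.columns:
            cols["body_weight"] = self.cohort.body_weight().reindex(subjects)
        col_df = pd.DataFrame(cols, index=subjects)
        correlations = correlation_matrix(col_df)

        # bootstrap comparisons of dependent overlapping correlations -----
        bootstrap: dict[str, BootstrapComparison] = {}
        if bootstrap_replicates > 0:
            if seed is None:
                raise ValueError("bootstrap comparisons require an explicit seed")
            comparisons = bootstrap_comparisons
            if comparisons is None:
                comparisons = []
                if "CA-BCS" in cols and "OCS" in cols:
                    comparisons.append(("CA-BCS", "MV", "OCS"))
                if "body_weight" in cols and "CA-BCS" in cols:
                    comparisons.append(("body_weight", "CA-BCS", "MV"))
            for i, (xn, y1n, y2n) in enumerate(comparisons):
                complete = col_df[[xn, y1n, y2n]].dropna()
                bootstrap[f"rho({xn},{y1n}) vs rho({xn},{y2n})"] = (
                    bootstrap_dependent_rho_diff(
                        complete[xn],
                        complete[y1n],
                        complete[y2n],
                        replicates=bootstrap_replicates,
                        level=bootstrap_level,
                        seed=(int(seed) + 7919 * i) % (2**31),
                    )
                )

        # diagnosis shifts (single-score references only) -----------------
        shift_tables: dict[str, ShiftTable] = {}
        if all(len(k.key_scores) == 1 for k in keys.values()):
            ref_scores = {s: next(iter(keys[s].key_scores)) for s in subjects}
            sub_votes = {s: votes[s] for s in subjects}
            for mode in BOUNDARY_MODES:
                shift_tables[mode] = cohort_shift_table(
                    ref_scores, sub, sub_votes, mode, ocs_rater=self.ocs_rater
                )

        # duplicate consistency -------------------------------------------
        duplicates: list[DuplicatePairReport] = []
        if self.registry is not None and self.registry.pairs:
            duplicates = duplicate_consistency(matrix, self.registry, votes)

        return AgreementResults(
            model=self,
            votes=votes,
            deviation_table=deviation_table,
            pooled_deviation=pooled,
            concordance=concordance,
            bland_altman=ba,
            correlations=correlations,
            bootstrap=bootstrap,
            shift_tables=shift_tables,
            duplicates=duplicates,
            seed=seed,
        )


def _vote_record(subject: str, vote: int, key: ReferenceKey):
    from .agreement import DeviationRecord

    d = signed_deviation(vote, key)
    return DeviationRecord(subject, "MV", d, abs(d))


@dataclass
class AgreementResults:
    """Fitted agreement analysis; see :class:`RaterAgreementModel`."""

    model: RaterAgreementModel
    votes: dict[str, VoteResult]
    deviation_table: pd.DataFrame
    pooled_deviation: DeviationSummary
    concordance: ConcordanceResult
    bland_altman: BlandAltmanResult
    correlations: CorrelationMatrixResult
    bootstrap: dict[str, BootstrapComparison]
    shift_tables: dict[str, ShiftTable]
    duplicates: list[DuplicatePairReport]
    seed: int | None = None
    conventions: tuple[str, ...] = (
        "majority-vote ties: nearest-to-remaining-scores, then nearest-to-median, then lower score",
        "two-score reference keys: closest key; equidistance broken toward the lower key",
        "SEM: sample SD of absolute deviations over pooled evaluations / sqrt(n)",
        "shift-rate denominator: all analysed subjects",
        "duplicate presentations excluded from deviation/shift pools when the reference is per-animal",
    )

    def summary(self) -> str:
        """Human-readable analysis summary (all numbers recomputable)."""
        m = self.model
        lines = [
            "Multi-rater BCS agreement analysis",
            "=" * 50,
            f"subjects analysed: {len(m.analysis_subjects)}"
            f" (of {m.matrix.n_subjects} presented)",
            f"raters: {m.matrix.n_raters}; reference mode: {m.mode}",
            "",
            "Deviation from reference (pooled over evaluated raters):",
            f"  mean |dev| = {self.pooled_deviation.mean_abs:.2f}"
            f" +/- {self.pooled_deviation.sem:.2f} SEM"
            f" (n = {self.pooled_deviation.n} evaluations)",
            f"  complete agreement = {100 * self.pooled_deviation.complete_agreement_fraction:.1f}%",
            "",
            "Per-evaluator deviation:",
        ]
        tbl = self.deviation_table.copy()
        for label, row in tbl.iterrows():
            p = "" if np.isnan(row["p_vs_vote"]) else f"  p(vs vote)={row['p_vs_vote']:.5f}"
            lines.append(
                f"  {label:<10} {row['mean_abs_deviation']:.2f} +/- {row['sem']:.2f}"
                f"  agree {100 * row['complete_agreement']:5.1f}%{p}"
            )
        c = self.concordance
        lines += [
            "",
            f"Kendall's W = {c.W:.3f} (chi2 = {c.chi_square:.1f}, df = {c.df}, p = {c.p_value:.3g})",
            f"Bland-Altman: mean diff = {self.bland_altman.mean_difference:.3f},"
            f" limits ({self.bland_altman.limits[0]:.3f}, {self.bland_altman.limits[1]:.3f})",
        ]
        for mode, table in self.shift_tables.items():
            mv = next((s for s in table.summaries if s.evaluator_id == "MV"), None)
            lines.append(
                f"Diagnosis shifts [{mode}]: scorer average = "
                f"{100 * table.average_rate:.1f}%"
                + (f", vote = {100 * mv.shift_rate:.1f}%" if mv else "")
            )
        for name, bc in self.bootstrap.items():
            lines.append(
                f"Bootstrap {name}: delta = {bc.delta:.3f}, "
                f"{int(bc.level * 100)}% CI ({bc.ci[0]:.3f}, {bc.ci[1]:.3f}), p = {bc.p_value:.3f}"
            )
        for rep in self.duplicates:
            lines.append(
                f"Duplicate pair {rep.pair}: votes {rep.votes[0]} -> {rep.votes[1]}"
                f" (vote diff {rep.vote_diff:+d})"
            )
        return "\n".join(lines)

    # -- serialization ----------------------------------------------------

    def to_csv_bundle(self, outdir: str | Path) -> list[Path]:
        """Write the full report bundle as deterministic CSV/text files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []

        def _write(frame: pd.DataFrame, name: str, index: bool = True) -> None:
            p = outdir / name
            frame.to_csv(p, index=index, encoding="utf-8")
            written.append(p)

        _write(self.deviation_table, "deviation_table.csv")
        c = self.concordance
        _write(
            pd.DataFrame(
                [
                    {
                        "W": c.W,
                        "chi_square": c.chi_square,
                        "df": c.df,
                        "p_value": c.p_value,
                        "n_subjects": c.n_subjects,
                        "n_raters": c.n_raters,
                    }
                ]
            ),
            "kendalls_w.csv",
            index=False,
        )
        ba = self.bland_altman
        _write(ba.points, "bland_altman_points.csv", index=False)
        _write(
            pd.DataFrame(
                [
                    {
                        "mean_difference": ba.mean_difference,
                        "sd_difference": ba.sd_difference,
                        "lower_limit": ba.limits[0],
                        "upper_limit": ba.limits[1],
                    }
                ]
            ),
            "bland_altman.csv",
            index=False,
        )
        _write(self.correlations.rho, "correlation_rho.csv")
        _write(self.correlations.p, "correlation_p.csv")
        if self.bootstrap:
            _write(
                pd.DataFrame(
                    [
                        {
                            "comparison": name,
                            "rho_1": b.rho_1,
                            "rho_2": b.rho_2,
                            "delta": b.delta,
                            "ci_lower": b.ci[0],
                            "ci_upper": b.ci[1],
                            "p_value": b.p_value,
                            "replicates": b.replicates,
                            "level": b.level,
                            "seed": b.seed,
                            "n": b.n,
                            "n_redrawn": b.n_redrawn,
                        }
                        for name, b in self.bootstrap.items()
                    ]
                ),
                "bootstrap_comparisons.csv",
                index=False,
            )
        for mode, table in self.shift_tables.items():
            _write(table.to_frame(), f"shift_{mode}.csv", index=False)
        if self.duplicates:
            rows = []
            for rep in self.duplicates:
                for rater, d in rep.rater_diffs.items():
                    rows.append(
                        {
                            "subject_a": rep.pair[0],
                            "subject_b": rep.pair[1],
                            "rater": rater,
                            "score_difference": d,
                            "vote_a": rep.votes[0],
                            "vote_b": rep.votes[1],
                            "vote_difference": rep.vote_diff,
                        }
                    )
            _write(pd.DataFrame(rows), "duplicate_pairs.csv", index=False)

        log = outdir / "run_log.txt"
        log.write_text(
            "\n".join(
                [
                    f"bcsagree version: {__version__}",
                    f"reference mode: {self.model.mode}",
                    f"dedup duplicates: {self.model.dedup}",
                    f"seed: {self.seed}",
                    "conventions in force:",
                    *[f"  - {c}" for c in self.conventions],
                    "",
                ]
            ),
            encoding="utf-8",
        )
        written.append(log)
        return written
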