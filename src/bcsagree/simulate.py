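"""Synthetic multi-rater cohort generator.

Generates cohorts with the statistical structure the agreement analysis
assumes, so the whole pipeline is testable without any external data:

* a categorical **true BCS** per subject, drawn from a configurable
  distribution (the default mirrors a clinic population of adult cats:
  support 4-9, median 6, roughly 40% ideal weight / 32% overweight /
  29% obese);
* a **body weight** per subject, log-linear in the true score with
  log-normal noise, so weight is rank-correlated with condition (the
  default noise level is calibrated for Spearman rho ~= 0.73);
* a **rater score matrix**: each rater perceives the true score through a
  discretized-Gaussian channel, score = clamp(round(truth + bias + eps),
  1, 9) with eps ~ N(0, dispersion^2).  Bias and dispersion are per rater;
  tiers (senior / clinician / student) are labels only;
* optional **duplicate pairs**: selected subjects are re-presented under a
  perturbed perceived truth (a -1/0/+1 presentation shift applied to all
  raters alike, emulating pose/angle effects), with the pair recorded in a
  duplicate registry.

All randomness flows from explicit seeds; identical (config, seed) yields
byte-identical serialized cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import CohortTable, DuplicateRegistry, ScoreMatrix

__all__ = [
    "RaterModel",
    "WeightModel",
    "CohortConfig",
    "SyntheticCohort",
    "default_raters",
    "default_config",
    "generate_truth_and_weights",
    "generate_rater_scores",
    "inject_duplicates",
    "generate_cohort",
    "calibrate_weight_model",
    "load_cohort_config",
]


@dataclass(frozen=True)
class RaterModel:
    """One simulated rater: mean shift and perceptual noise in score units."""

    rater_id: str
    bias: float = 0.0
    dispersion: float = 0.6
    tier: str = "clinician"  # label only: senior | clinician | student

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass(frozen=True)
class WeightModel:
    """Log-linear body-weight model: w = exp(intercept + slope*truth + eps).

    ``intercept``/``slope`` are on the log-kg scale (slope per score unit);
    ``log_sd`` is the SD of the log-normal noise eps.
    """

    intercept: float = 0.89
    slope: float = 0.12
    log_sd: float = 0.175

    def __post_init__(self) -> None:
        if self.log_sd < 0:
            raise ValueError("log_sd must be >= 0")


#: Truth-score distribution of a clinic-like cohort: support 4-9, median 6,
#: 15/38 ideal weight, 12/38 overweight, 11/38 obese.
DEFAULT_TRUTH_DISTRIBUTION: dict[int, float] = {
    4: 3 / 38,
    5: 12 / 38,
    6: 8 / 38,
    7: 4 / 38,
    8: 6 / 38,
    9: 5 / 38,
}


def default_raters() -> list[RaterModel]:
    """Nine raters in the study's tier design: 2 senior, 3 clinicians, 4 students."""
    senior = [RaterModel(r, 0.0, 0.4, "senior") for r in "AB"]
    clin = [RaterModel(r, 0.0, 0.6, "clinician") for r in "CDE"]
    stud = [RaterModel(r, 0.0, 0.6, "student") for r in "FGHI"]
    return senior + clin + stud


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort."""

    n_subjects: int = 38
    truth_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUTH_DISTRIBUTION)
    )
    raters: tuple[RaterModel, ...] = field(default_factory=lambda: tuple(default_raters()))
    weight_model: WeightModel = field(default_factory=WeightModel)
    n_duplicate_pairs: int = 2
    duplicate_perturbation: Mapping[int, float] = field(
        default_factory=lambda: {-1: 0.25, 0: 0.5, 1: 0.25}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        _check_probs(self.truth_distribution, scores=True)
        _check_probs(self.duplicate_perturbation, scores=False)
        if self.n_duplicate_pairs > self.n_subjects:
            raise ValueError("cannot duplicate more subjects than exist")


def _check_probs(dist: Mapping[int, float], scores: bool) -> None:
    if not dist:
        raise ValueError("empty probability mapping")
    total = float(sum(dist.values()))
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError(f"probabilities must sum to 1 (got {total})")
    if any(p < 0 for p in dist.values()):
        raise ValueError("probabilities must be nonnegative")
    if scores and any(not 1 <= int(k) <= 9 for k in dist):
        raise ValueError("truth scores must lie in 1-9")
    if not scores and any(int(k) not in (-1, 0, 1) for k in dist):
        raise ValueError("perturbations must lie in {-1, 0, +1}")


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """The package's reference study conditions with an explicit seed."""
    return replace(CohortConfig(seed=seed), **overrides)


@dataclass
class SyntheticCohort:
    """A generated cohort: truth, weights, rater matrix, registry, metadata.

    ``truth`` holds the animal's true score per subject (duplicates carry
    their source animal's truth); ``perceived_truth`` differs from
    ``truth`` only for duplicates whose presentation was perturbed.
    """

    truth: pd.Series
    perceived_truth: pd.Series
    weights: pd.Series
    matrix: ScoreMatrix
    registry: DuplicateRegistry
    cohort: CohortTable
    config: CohortConfig
    seed: int


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_truth_and_weights(
    config: CohortConfig, seed: int | np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw true scores and log-linear body weights.

    weight_i = exp(intercept + slope * truth_i + eps_i), eps ~ N(0, log_sd).
    """
    rng = _as_rng(config.seed if seed is None else seed)
    scores = np.array(sorted(config.truth_distribution), dtype=int)
    probs = np.array([config.truth_distribution[int(s)] for s in scores], dtype=float)
    probs = probs / probs.sum()
    truth = rng.choice(scores, size=config.n_subjects, p=probs)
    wm = config.weight_model
    eps = rng.normal(0.0, wm.log_sd, size=config.n_subjects) if wm.log_sd > 0 else 0.0
    weights = np.exp(wm.intercept + wm.slope * truth + eps)
    return truth, weights


def generate_rater_scores(
    truth: Sequence[int],
    raters: Sequence[RaterModel],
    seed: int | np.random.Generator | None = None,
    subjects: Sequence[str] | None = None,
) -> ScoreMatrix:
    """Score matrix from the discretized-Gaussian rater channel.

    score = clamp(round(truth + bias + dispersion * z), 1, 9) with a single
    standard-normal draw z per (subject, rater); the same seed therefore
    yields common random numbers across dispersion settings, making
    noise-sweep comparisons exactly paired.
    """
    truth = np.asarray(truth, dtype=float)
    rng = _as_rng(seed)
    z = rng.standard_normal(size=(truth.size, len(raters)))
    cols = {}
    for j, r in enumerate(raters):
        raw = np.round(truth + r.bias + r.dispersion * z[:, j])
        cols[r.rater_id] = np.clip(raw, 1, 9).astype(int)
    if subjects is None:
        subjects = [str(i + 1) for i in range(truth.size)]
    frame = pd.DataFrame(cols, index=list(subjects), dtype="Float64")
    return ScoreMatrix(frame)


def _assemble(
    config: CohortConfig,
    subjects: list[str],
    truth: np.ndarray,
    perceived: np.ndarray,
    weights: np.ndarray,
    matrix: ScoreMatrix,
    registry: DuplicateRegistry,
) -> SyntheticCohort:
    cohort_df = pd.DataFrame(
        {
            "body_weight_kg": weights,
            "ca_bcs": truth.astype(int),
        },
        index=subjects,
    )
    return SyntheticCohort(
        truth=pd.Series(truth.astype(int), index=subjects),
        perceived_truth=pd.Series(perceived.astype(int), index=subjects),
        weights=pd.Series(weights, index=subjects),
        matrix=matrix,
        registry=registry,
        cohort=CohortTable(cohort_df),
        config=config,
        seed=config.seed,
    )


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> SyntheticCohort:
    """Generate a full cohort (truth, weights, scores, optional duplicates).

    Child streams for truth/weights, rater noise, and duplicate injection
    are spawned from one seed sequence, so the cohort is fully reproducible
    from ``config.seed`` (or the ``seed`` override).
    """
    if config is None:
        config = CohortConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    ss = np.random.SeedSequence(config.seed)
    rng_truth, rng_scores, rng_dup = (np.random.default_rng(c) for c in ss.spawn(3))
    truth, weights = generate_truth_and_weights(config, rng_truth)
    subjects = [str(i + 1) for i in range(config.n_subjects)]
    matrix = generate_rater_scores(truth, config.raters, rng_scores, subjects)
    cohort = _assemble(
        config, subjects, truth, truth.copy(), weights, matrix, DuplicateRegistry([])
    )
    if config.n_duplicate_pairs > 0:
        cohort = inject_duplicates(
            cohort, config.n_duplicate_pairs, config.duplicate_perturbation, rng_dup
        )
    return cohort


def inject_duplicates(
    cohort: SyntheticCohort,
    n_pairs: int,
    perturbation_probs: Mapping[int, float],
    seed: int | np.random.Generator | None = None,
) -> SyntheticCohort:
    """Append duplicated presentations of randomly chosen subjects.

    The duplicate's *perceived* truth is the source truth shifted by
    delta in {-1, 0, +1} (clamped to 1-9) — the shift acts on the stimulus,
    so all raters are displaced in the same direction.  Rater scores for
    the duplicates are regenerated from the perceived truth; cohort rows
    carry the source animal's weight and true score.
    """
    _check_probs(perturbation_probs, scores=False)
    existing = list(cohort.matrix.subjects)
    eligible = [s for s in existing if s not in cohort.registry.members]
    if n_pairs > len(eligible):
        raise ValueError(f"cannot inject {n_pairs} pairs: only {len(eligible)} eligible subjects")
    rng = _as_rng(seed)
    sources = list(rng.choice(eligible, size=n_pairs, replace=False))
    deltas = np.array(sorted(perturbation_probs), dtype=int)
    probs = np.array([perturbation_probs[int(d)] for d in deltas], dtype=float)
    probs = probs / probs.sum()

    next_id = 1 + max((int(s) for s in existing if s.isdigit()), default=0)
    dup_ids = [str(next_id + k) for k in range(n_pairs)]
    src_truth = cohort.truth.loc[sources].to_numpy()
    shift = rng.choice(deltas, size=n_pairs, p=probs)
    perceived = np.clip(src_truth + shift, 1, 9)
    dup_matrix = generate_rater_scores(
        perceived, list(cohort.config.raters), rng, subjects=dup_ids
    )

    frame = pd.concat([cohort.matrix.frame, dup_matrix.frame])
    matrix = ScoreMatrix(frame)
    registry = DuplicateRegistry(
        list(cohort.registry.pairs) + list(zip(sources, dup_ids))
    )
    truth = pd.concat([cohort.truth, pd.Series(src_truth, index=dup_ids)])
    perceived_truth = pd.concat([cohort.perceived_truth, pd.Series(perceived, index=dup_ids)])
    weights = pd.concat([cohort.weights, cohort.weights.loc[sources].set_axis(dup_ids)])
    return _assemble(
        cohort.config,
        list(truth.index),
        truth.to_numpy(),
        perceived_truth.to_numpy(),
        weights.to_numpy(),
        matrix,
        registry,
    )


def calibrate_weight_model(
    target_rho: float,
    truth_distribution: Mapping[int, float] | None = None,
    n_calibration: int = 10_000,
    seed: int = 0,
    slope: float = 0.12,
    intercept: float = 0.89,
    tol: float = 0.02,
) -> tuple[WeightModel, float]:
    """Find the log-noise SD giving a target Spearman(truth, weight).

    The slope is held fixed and the log-scale noise SD is bisected until
    the simulated rank correlation at ``n_calibration`` subjects is within
    ``tol`` of ``target_rho``.  Common random numbers (one truth draw, one
    noise draw, noise scaled by the candidate SD) make the objective
    strictly monotone in the SD.  Returns the model and the achieved rho.
    """
    from .stats import spearman_rho

    if not 0.0 < target_rho < 1.0:
        raise ValueError("target_rho must lie strictly between 0 and 1")
    dist = dict(truth_distribution or DEFAULT_TRUTH_DISTRIBUTION)
    _check_probs(dist, scores=True)
    if len(dist) < 2 or sum(p > 0 for p in dist.values()) < 2:
        raise ValueError("truth distribution must have at least 2 support points")
    rng = np.random.default_rng(seed)
    scores = np.array(sorted(dist), dtype=int)
    probs = np.array([dist[int(s)] for s in scores], dtype=float)
    probs = probs / probs.sum()
    truth = rng.choice(scores, size=n_calibration, p=probs)
    noise = rng.standard_normal(n_calibration)

    def achieved(log_sd: float) -> float:
        w = np.exp(intercept + slope * truth + log_sd * noise)
        return spearman_rho(truth, w).rho

    lo, hi = 0.0, 0.05
    while achieved(hi) > target_rho:
        hi *= 2.0
        if hi > 64.0:
            raise ValueError(
                f"target rho {target_rho} unattainable for this truth distribution"
            )
    if achieved(lo) < target_rho - tol:
        raise ValueError(
            f"target rho {target_rho} exceeds the zero-noise maximum for this distribution"
        )
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        r = achieved(mid)
        if abs(r - target_rho) <= tol * 0.5 or hi - lo < 1e-9:
            break
        if r > target_rho:
            lo = mid
        else:
            hi = mid
    else:  # pragma: no cover - bisection always terminates far earlier
        mid = 0.5 * (lo + hi)
        r = achieved(mid)
    return WeightModel(intercept=intercept, slope=slope, log_sd=mid), float(r)


def load_cohort_config(path: str | Path) -> CohortConfig:
    """Load a :class:`CohortConfig` from YAML (or JSON; YAML is a superset).

    Recognised keys mirror the dataclass fields; ``seed`` is mandatory.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    if "seed" not in raw:
        raise ValueError(f"{path}: config must state an explicit seed")
    kwargs: dict = {"seed": int(raw["seed"])}
    if "n_subjects" in raw:
        kwargs["n_subjects"] = int(raw["n_subjects"])
    if "truth_distribution" in raw:
        kwargs["truth_distribution"] = {
            int(k): float(v) for k, v in raw["truth_distribution"].items()
        }
    if "raters" in raw:
        kwargs["raters"] = tuple(
            RaterModel(
                rater_id=str(r["rater_id"]),
                bias=float(r.get("bias", 0.0)),
                dispersion=float(r.get("dispersion", 0.6)),
                tier=str(r.get("tier", "clinician")),
            )
            for r in raw["raters"]
        )
    if "weight_model" in raw:
        wm = raw["weight_model"]
        kwargs["weight_model"] = WeightModel(
            intercept=float(wm.get("intercept", 0.89)),
            slope=float(wm.get("slope", 0.12)),
            log_sd=float(wm.get("log_sd", 0.175)),
        )
    if "n_duplicate_pairs" in raw:
        kwargs["n_duplicate_pairs"] = int(raw["n_duplicate_pairs"])
    if "duplicate_perturbation" in raw:
        kwargs["duplicate_perturbation"] = {
            int(k): float(v) for k, v in raw["duplicate_perturbation"].items()
        }
    return CohortConfig(**kwargs)
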