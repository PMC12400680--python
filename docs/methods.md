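# Methods

This note documents the statistical conventions, the synthetic-data model,
and the design choices made where the problem admitted more than one
defensible answer. Everything stated here is implemented and exercised by
the test suite; no empirical claim is made that the tests or
`scripts/acceptance.py` do not themselves compute.

## Data model

The central object is the **score matrix**: an ordered subjects × raters
table of ordinal body-condition scores (1–9) with missing entries allowed.
Missing evaluations are excluded pairwise from every downstream statistic;
the fully complete design is the special case. Subject and rater
identifiers are opaque text and all outputs preserve input (file) order,
so every report is deterministic.

Score cells may carry a confidence annotation in three grammars:
`"n"` (plain), `"n = n"` (level A — fully confident), `"n = m"` with
adjacent m ≠ n (level B — two adjacent scores equally likely), and
`"n > m"` (level C — leaning toward the first). The matrix value is
always the **first-listed** score: for level C that is the leaned-toward
score by construction, and for level B — where the annotation itself is
symmetric — first-listed is the only order-free convention available.
Non-adjacent pairs are rejected as parse errors. Confidence levels never
enter any statistic; they are carried for bookkeeping only.

## Majority vote

The consensus score of a subject is the most frequent score among its
raters. Ties among modal candidates are resolved by a documented,
deterministic chain that uses only multisets (hence is invariant to rater
order):

1. the candidate with the smallest mean absolute distance to the multiset
   of remaining (non-candidate) scores;
2. failing that (no remaining scores, or still tied), the candidate
   closest to the median of all scores;
3. failing that, the **lower** score.

The lower-score fallback is deliberately conservative: when the evidence
is perfectly balanced the vote biases against over-diagnosis. The vote
always lies within `[min(scores), max(scores)]` and is verified against
exhaustive enumeration of all small score multisets.

## Deviation from a reference

When the reference is a two-clinician pair, each evaluation is compared
with the **closest** key score; exact equidistance between the two keys is
broken toward the lower key (the same conservative convention as the
vote). The pooled summary reports the mean absolute deviation, the SEM
computed as the sample (n−1) SD of the absolute deviations over all pooled
evaluations divided by √n, the distribution of signed deviations, and the
complete-agreement fraction. SEM over evaluations (rather than over
per-subject means) is the definition consistent with per-scorer summaries
at n = number of subjects.

When a duplicate registry is present and the reference is per-animal
(a clinical score), the injected duplicate presentations are excluded from
the deviation, correlation, and diagnosis pools — each animal contributes
once per evaluator — and are analysed separately in the duplicate-pair
report. Concordance (below) is computed on the full presented matrix,
since it concerns the raters' internal consistency across everything they
scored.

## Concordance, Bland–Altman, and rank tests

**Kendall's W** uses mid-ranks within each rater's column and the ties
correction `W = 12·S / (m²(n³−n) − m·ΣT_j)`, with `T_j = Σ(t³−t)` over
tied groups of rater j. Significance uses the χ² approximation
`χ² = m(n−1)W` on n−1 df, standard for the cohort sizes involved (≥ ~7
subjects); exact permutation p-values are out of scope. Subjects with any
missing score are dropped listwise for W. A matrix in which every rater
assigns a constant score makes the ties correction consume the whole
denominator and is reported as a degenerate-input error.

**Bland–Altman** reports the mean paired difference, its sample SD, and
limits of agreement at ±1.96 SD. In the fitted model, series *a* is the
per-subject mean of the evaluated raters' scores and series *b* the
(closest) reference.

**Rank tests.** The Wilcoxon signed-rank test discards zero differences
and uses the exact null distribution of T⁺ for ≤ 25 nonzero differences —
computed by dynamic programming over doubled mid-ranks, so tied
differences are handled exactly (verified against full 2ⁿ enumeration) —
and the tie/continuity-corrected normal approximation beyond that. The
Mann–Whitney U test is exact for small untied samples (n₁·n₂ ≤ 400) and
tie-corrected asymptotic otherwise. Fisher's exact test sums 2×2 tables
with hypergeometric probability ≤ the observed table. The fixed
exact-vs-approximate thresholds make p-values reproducible across
platforms.

**Spearman correlations** mid-rank both vectors and take the
product-moment correlation of the ranks, with the t approximation on n−2
df; pairwise deletion is used cell by cell in the correlation matrix, and
cells with fewer than 3 complete pairs or a constant rank vector are
flagged undefined rather than filled.

## Bootstrap comparison of dependent overlapping correlations

Two correlations ρ(x,y₁) and ρ(x,y₂) sharing x on the same subjects are
compared by resampling **subjects** with replacement (which preserves the
y₁–y₂ dependence through the shared index), recomputing both correlations
per replicate, and forming the replicate distribution of
Δ = ρ(x,y₁) − ρ(x,y₂). The interval is the percentile interval; the
two-sided p-value is the symmetric sign-crossing proportion
`2·min(P(Δ* ≤ 0), P(Δ* ≥ 0))` clipped to [0,1] — the standard
percentile-bootstrap convention, documented here because the construction
is not uniquely determined by naming the routine. Replicates whose
resample makes a correlation undefined (a constant vector) are redrawn so
the replicate count stays fixed; the redraw count is recorded. Results
are bit-reproducible from the seed. The suite measures the empirical
type-I error of this test at n = 50 under an exchangeable null (500
datasets × 1,000 replicates): it must fall within 0.05 ± 0.02.

## Diagnostic categories and shift rates

Scores map onto ordered categories UW (1–3), IW (4–5), OW (6–7), OB
(8–9). Two boundary modes are reported: crossings of the IW | (OW ∪ OB)
boundary in either direction, and moves strictly between IW and OB. The
denominator is **all** analysed subjects in both modes (not the subset in
the two categories) — under this convention a vote that shifts 3 of 38
animals yields 3/38 ≈ 7.9%. The across-evaluator average is the
unweighted mean of the individual raters' rates; the vote (and the
duplicated OCS row) is excluded from that average. A restricted-denominator
variant can be derived from the emitted counts but is not the reported
rate.

## Synthetic cohort model

The generator emulates the statistical structure the analysis assumes:

- **Truth scores** are i.i.d. categorical. The default distribution has
  support 4–9 with median 6 and category mass 15/38 IW, 12/38 OW, 11/38 OB
  — a clinic-like population of adult cats in which underweight animals
  are absent.
- **Body weight** is log-linear in truth:
  `w = exp(0.89 + 0.12·truth + ε)`, ε ~ N(0, σ²_log). The intercept and
  slope put an ideal-condition cat near 4.5 kg with ~13% weight per score
  point; σ_log defaults to 0.175, fixed once by running
  `calibrate_weight_model` (bisection on σ_log with common random numbers)
  to a target truth–weight Spearman correlation of 0.73, the value
  reported for palpation-based scores against measured weight.
- **Raters** perceive truth through a discretized-Gaussian channel:
  `score = clamp(round(truth + bias + dispersion·z), 1, 9)`. Defaults are
  nine raters in the 2 senior / 3 clinician / 4 student design with
  dispersions 0.4 / 0.6 / 0.6 and zero biases; these are modelling knobs,
  not estimates. Rounding is IEEE half-to-even. One z draw per
  (subject, rater) from the seed means dispersion sweeps at a fixed seed
  are exactly paired (common random numbers), which the monotonicity tests
  exploit.
- **Duplicates**: selected subjects are re-presented with a perceived
  truth shifted by δ ∈ {−1, 0, +1} (default probabilities 0.25/0.5/0.25).
  The shift acts on the stimulus, not per rater — matching the observation
  that a pose/angle change displaces all evaluators in the same direction.
  Duplicate rows carry their source animal's weight and true score.

Default cohort size is 38 animals plus 2 duplicate pairs (40
presentations), the size at which all pipeline paths (dedup, registry,
OCS handling) are exercised in seconds.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: systematic rater biases (defaults are zero, so
the simulated majority vote recovers truth almost perfectly, unlike real
cohorts where the vote still deviates from the clinical reference);
heteroscedastic difficulty (long-haired or dark-coated animals);
correlated errors between raters beyond the shared stimulus; confidence
annotations; and any image-level effects. The generator's role is to
provide cohorts with known truth for verifying the estimators, not to
reproduce any particular empirical cohort's numbers.

## Numerical and degenerate-input conventions

- All randomness requires explicit seeds; there is no global seeding.
  Child streams are spawned via `numpy` seed sequences.
- Degenerate inputs are errors when the statistic is undefined (empty
  vote list, empty reference key, all-tied concordance matrix, constant
  correlation vector) and warnings with the conventional value when a
  limit exists (all-zero paired differences → p = 1; zero-margin 2×2
  table → p = 1).
- Equidistance and ties are always broken toward the **lower** score, in
  the vote fallback and the closest-key rule alike.
- Problem sizes in the test suite (e.g. 500 bootstrap calibration
  datasets of n = 50 with 1,000 replicates; dispersion sweeps at n =
  1,000; calibration at n = 10,000) were chosen so Monte-Carlo error is
  small relative to the asserted tolerances while the whole suite runs in
  well under a minute.

## Known limitations

- The tie-break chain is *a* defensible operationalisation of
  "use the remaining scores"; other conventions (e.g. highest-count-then-
  random) would change vote-dependent numbers on tied subjects. It is
  therefore documented, deterministic, and isolated in one function.
- Kendall's W p-values rely on the χ² approximation; do not trust them
  below ~7 subjects.
- The bootstrap p-value is a percentile sign-crossing construction, not a
  studentised bootstrap; at very small n (< ~20) it can be mildly
  anti-conservative.
- Level-B confidence records collapse to the first-listed score; if a
  data source orders them differently the matrix values change.
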