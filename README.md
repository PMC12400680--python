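# bcsagree

Multi-rater agreement analysis for ordinal **body condition scores (BCS)**.

Body condition scoring on the 9-point scale (1–3 underweight, 4–5 ideal,
6–7 overweight, 8–9 obese) is the standard semi-quantitative measure of
adiposity in companion animals. When several evaluators score the same
animals — for instance from photographs, as in telemedicine or large
epidemiological studies — the scores disagree, and the analysis questions
are: *how much*, *does a consensus vote help*, and *does the disagreement
change the clinical diagnosis?*  `bcsagree` is a tested, reusable pipeline
for exactly this design: a subjects × raters table of ordinal scores,
optionally accompanied by a clinical reference score, body weights, and
duplicated stimuli inserted as integrity checks.

## What it computes

For a score matrix $X_{ij}$ (subject $i$, rater $j$, $X_{ij}\in\{1..9\}$):

- **Majority-vote consensus** $\mathrm{MV}_i = \operatorname{mode}_j X_{ij}$,
  with a deterministic, permutation-invariant tie-break (nearest to the
  remaining scores, then nearest to the median, then the lower score).
- **Deviation statistics** against a per-subject reference key $K_i$ (a
  clinical score, or a two-clinician pair where the *closest* key is used):
  $d_{ij} = X_{ij} - \arg\min_{k \in K_i}|X_{ij}-k|$, summarised as the
  pooled mean $|d|$ ± SEM, the signed-deviation distribution, and the
  complete-agreement fraction, plus paired Wilcoxon signed-rank tests of
  each evaluator against the vote.
- **Kendall's coefficient of concordance** with the mid-rank ties
  correction, $W = \dfrac{12S}{m^2(n^3-n) - m\sum_j T_j}$, tested via
  $\chi^2 = m(n-1)W$ on $n-1$ df.
- **Bland–Altman limits of agreement**, mean difference ± 1.96 SD.
- **Spearman correlation matrices** (raters, vote, clinical score, body
  weight) and a subject-level **bootstrap comparison of two dependent
  overlapping correlations** $\rho(x,y_1)$ vs $\rho(x,y_2)$ (percentile CI
  and sign-crossing two-sided p, default 5,000 replicates).
- **Diagnosis-shift analysis**: how often a rater's score moves an animal
  across the ideal-weight | overweight/obese boundary, or between ideal
  weight and obese proper.
- A **synthetic cohort generator** (truth distribution, per-rater
  bias/dispersion, log-linear body weights calibrated to a target rank
  correlation, perturbed duplicate presentations) so the entire pipeline is
  testable end to end without any data downloads.

## Worked example

```python
from bcsagree import RaterAgreementModel
from bcsagree.simulate import default_config, generate_cohort

cohort = generate_cohort(default_config(seed=1))   # 38 animals + 2 duplicates, 9 raters
model = RaterAgreementModel(cohort.matrix, "ca_bcs", cohort=cohort.cohort,
                            registry=cohort.registry, ocs_rater="A")
results = model.fit(bootstrap_replicates=5000, seed=2)
print(results.summary())
```

```
Multi-rater BCS agreement analysis
==================================================
subjects analysed: 38 (of 40 presented)
raters: 9; reference mode: ca_bcs

Deviation from reference (pooled over evaluated raters):
  mean |dev| = 0.30 +/- 0.03 SEM (n = 342 evaluations)
  complete agreement = 70.2%

Per-evaluator deviation:
  Scorer A   0.21 +/- 0.07  agree  78.9%  p(vs vote)=0.00781
  Scorer B   0.11 +/- 0.05  agree  89.5%  p(vs vote)=0.12500
  ...
  Vote       0.00 +/- 0.00  agree 100.0%

Kendall's W = 0.886 (chi2 = 311.0, df = 39, p = 4.24e-44)
Bland-Altman: mean diff = -0.015, limits (-0.401, 0.372)
Diagnosis shifts [IW_vs_OWOB]: scorer average = 6.1%, vote = 0.0%
Diagnosis shifts [IW_vs_OB]: scorer average = 0.0%, vote = 0.0%
Bootstrap rho(CA-BCS,MV) vs rho(CA-BCS,OCS): delta = 0.047, 95% CI (0.018, 0.093), p = 0.000
Duplicate pair ('9', '39'): votes 6 -> 7 (vote diff +1)
```

Reading the output: the nine simulated raters individually deviate from
the clinical reference by 0.11–0.42 points on average, and agree with it
exactly on 58–90% of animals; their concordance is high (W = 0.886).  The
majority vote removes essentially all individual error here (mean
deviation 0.00, every paired Wilcoxon p < 0.05 except the best rater),
and no animal's obesity diagnosis (ideal weight vs obese) is changed by
any rater.  The two duplicated presentations were voted within one point
of each other, as designed.

The same analysis runs from CSV files
(`RaterAgreementModel.from_csv(...)`) or from the command line:

```bash
bcsagree simulate --seed 1 --out out/           # synthetic cohort + full report
bcsagree report --scores scores.csv --cohort cohort.csv \
    --reference ca_bcs --ocs A --bootstrap-reps 5000 --seed 2 --out out/
bcsagree validate|consensus|agreement|correlate|diagnose ...
```

`report` writes a deterministic CSV bundle: the per-evaluator deviation
table, Kendall's W, Bland–Altman points and limits, correlation and
p-value matrices, bootstrap comparisons, shift tables for both category
boundaries, the duplicate-pair report, and a run log recording seeds and
the tie-break/closest-key conventions in force.

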