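# Methods

## Model and procedure

The pipeline treats mesh-derived BSA as the criterion measurement and each
predictive equation as an index test. For subject *i* with weight *Wᵢ* (kg)
and height *Hᵢ* (cm):

* criterion: `refᵢ = mean over replicate scans of Σ_faces ½·|(p₁−p₀)×(p₂−p₀)|`,
  vertices in metres, winding ignored (absolute areas), no mesh repair;
* index test *m*: `predᵢₘ = fₘ(Wᵢ, Hᵢ, sexᵢ)` with the ten registered
  equations stored exactly as printed in their common clinical form
  (power laws `c·W^a·H^b`, one affine chart fit, one weight-only law).

Agreement per method and sex: Pearson r; `RMSE = √mean((pred−ref)²)`;
relative differences `dᵢ = 100·(predᵢ−refᵢ)/refᵢ` summarised as mean ± SD
(n−1), with the criterion in the denominator (the standard
method-comparison convention when one method is the reference);
Bland–Altman mean difference, limits of agreement at mean ± 1.96·SD, and
proportional bias as the Pearson correlation of differences vs pairwise
means with its two-sided p. The omnibus across the criterion and ten
equations is chosen by a normality gate: Shapiro–Wilk on each method's
paired differences at α = 0.05; if all pass, one-way repeated-measures
ANOVA (statsmodels AnovaRM) with Bonferroni-corrected paired t tests
against the criterion, otherwise Friedman's rank ANOVA (in-package:
within-subject mid-ranks, tie-corrected χ² statistic) with
Bonferroni-corrected Wilcoxon signed-rank tests. Which branch fires is
recorded in the report; the gate decides the branch and nothing else.

Dilatation classification indexes LVEDD (mm), LVEDV (ml) and RVBD (mm) by
a BSA source and compares strictly (`>`) against cut-points LVEDD 30/31
mm/m² (male/female), LVEDV 74/61 ml/m², RVBD 22 mm/m² (both sexes);
classification always uses unrounded indexes (1-decimal rounding is a
rendering convention). A subject dilated on both sides is presumed
athlete's heart — balanced, training-induced biventricular enlargement —
and is excluded from the prevalence numerator while remaining in the
denominator, so `left_only + right_only = numerator` always holds.
Prevalences under two normalizations are compared with McNemar's test on
the counted flags: exact two-sided binomial on the discordant counts
(b, c) when b + c < 25, continuity-corrected χ² otherwise.

Grubbs QC runs before the accuracy analysis on the pooled criterion-BSA
distribution: iteratively, the observation with the largest studentised
deviation `G = max|xᵢ−x̄|/s` is tested against
`G_crit = (n−1)/√n · √(t²/(n−2+t²))`, `t = t_{α/(2n), n−2}`, and removed if
significant, until no flag remains. Flagged subjects are excluded and
logged.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| Grubbs α | 0.05 | — | conventional outlier-screen level |
| normality-gate α | 0.05 | — | conventional; branch decision only |
| LoA multiplier | 1.96 | SDs | 95% limits of agreement |
| McNemar exact threshold | b+c < 25 | pairs | exact binomial cheap and preferable at small discordance |
| cut-points | 30/31, 74/61, 22 | mm/m², ml/m², mm/m² | current echocardiography guideline values; overridable per run |
| weight range guard | 20–150 kg | kg | outside triggers a unit warning, not an error |
| height range guard | 120–220 cm | cm | same |

The equations are algebraically defined everywhere, so out-of-range inputs
warn rather than raise: the guard exists to catch unit mistakes (grams,
metres), which silently produce absurd BSA otherwise.

One registry note: the widely reprinted Kuehnapfel coefficients
(0.015·W^0.4259·H^0.5751) evaluate to 1.920 m² for a 77 kg / 185 cm
athlete, while clinical write-ups of that example sometimes quote 1.933 m²
— consistent with the printed coefficients being rounded relative to the
original fit. The registry stores the printed coefficients verbatim and
does not re-derive or tune them; single-subject outputs therefore show
1.920 m² for this equation.

## The synthetic-data generator

Raw athlete records behind this kind of study are not publicly deposited,
so the generator reproduces their *structure*:

* **Anthropometry.** Height ~ truncated normal per sex; BMI ~ truncated
  normal matched to the reported per-sex medians/IQRs (SD = IQR/1.349);
  weight = BMI·(height m)². BMI rather than weight is modelled because
  cohort descriptions report BMI quartiles. Heights are not reported for
  these cohorts; defaults (imaging sample 177 ± 7 cm male, 165 ± 6 cm
  female; echo sample 179 ± 6.5 / 166 ± 6) are typical of youth soccer
  players. Default cohort sizes are 254/115 (imaging conditions) and
  86/25 (echo conditions) — the sample sizes the analysis is designed
  around.
* **Criterion BSA.** `ref = fᵣₑ𝒻(W,H,sex) / q`, with q lognormal
  parametrised to have arithmetic mean `1 + δ/100` and SD `cv/100`
  *exactly*, so the reference equation's relative difference vs the
  criterion has mean δ and SD cv in expectation with no small-sample moment
  bias. Defaults: reference = Kuehnapfel, δ = +2.2% (male) / +1.0%
  (female), cv = 4.3% / 4.7% — the accuracy observed for the
  best-performing equation, which makes every other (higher-predicting)
  equation overestimate the criterion in males, as observed. Noise is
  multiplicative lognormal throughout because BSA and echo measures are
  positive and the biases of interest are percent-scale.
* **Replicate scans.** Two draws of `ref·exp(σz − σ²/2)` (mean-one
  lognormal, cv 2%), so the replicate average is unbiased for the true
  criterion.
* **Echo measures.** `(slope·ref + offset_female)·lognormal(1, cv)`.
  Slopes and female offsets solve the published absolute medians on the
  criterion-BSA scale (male criterion median ≈ 1.81 m², female ≈ 1.63 m²
  under the echo-sample anthropometry): 28.7 mm/m² + 2.1 mm, 72.2 ml/m²
  − 13.0 ml, 21.5 mm/m² − 2.1 mm, with residual CVs 4/14/9% taken from the
  published IQR widths. This yields male absolute values above female ones
  while female *indexed* LVEDD exceeds male, matching the observed sign
  structure. When a target counted-prevalence is configured (echo-sample
  default: 26% under the Shuter normalization), a common multiplier on the
  three slopes is calibrated by coarse grid (0.7–1.5, 33 points) plus
  local refinement on the fixed noise draws; calibration failing to land
  within ±2 points raises rather than silently drifting.
* **Determinism.** Every draw descends from one integer seed
  (`numpy.random.default_rng`; the echo block uses a `SeedSequence`
  spawn), so a fixed seed reproduces cohorts byte-identically.

What the generator does **not** emulate: within-subject correlation between
echo variables beyond their shared dependence on BSA (not reported, assumed
conditionally independent); convenience-sampling selection effects;
scanner-specific mesh artifacts (occlusions, pose variation) — the
criterion is generated on the BSA scale directly, with mesh handling
exercised on geometric primitives instead. Passing tests therefore
demonstrate that the *pipeline* recovers known structure, not that any
equation is accurate in a particular real population.

## Numerical choices

* Exact-moment lognormal parametrisation: `σ² = ln(1+(s/m)²)`,
  `μ = ln m − σ²/2` for target mean m and SD s.
* Friedman: mid-ranks for ties, tie-corrected statistic; an exact
  permutation p (full enumeration over within-row orderings) is available
  for tiny designs and cross-checked against scipy's implementation in
  tests. All-constant rows give statistic 0, p 1.
* Degenerate inputs: zero-variance Bland–Altman differences report the
  proportional-bias correlation as absent; zero-variance cohorts give an
  undefined (NaN) Pearson r and omnibus rather than an error; a constant
  sample stops the Grubbs iteration with a warning; an empty face list has
  area 0 with a warning; a single scan passes through with a warning.
* Strict inequality at every cut-point: an index exactly at the cut-point
  is non-dilated.
* Shapiro–Wilk is evaluated on an evenly strided subsample when n > 5000,
  where the W approximation degrades; this affects only the branch
  decision.

## Problem sizes

The test suite and the acceptance script size their simulations to what
the checks need: n = 10,000 for moment-recovery (3 Monte-Carlo SEs ≈ 0.14
points on a 5.5% bias), n = 3,000 for the RMSE-ranking check, the study's
own 369/111 for the cohort-level runs, and 1,000 small random cohorts for
the flag-nesting property. The RMSE-ranking check uses an unbiased
Kuehnapfel-referenced criterion deliberately: with multiplicative noise of
CV c, the RMSE-minimising prediction scale sits O(c²) ≈ 0.2–0.4% below the
bias-minimising one, so the check is only meaningful when the least-biased
equation's margin over its nearest competitor (here ≥ ~1%) dominates that
shift.

## Known limitations

* The ten equations are evaluated as printed; no uncertainty in their
  coefficients is propagated.
* The Friedman exact path enumerates (k!)ⁿ tables and is gated to tiny
  designs; larger designs use the asymptotic χ² p.
* Z-score nomogram classification (age-adjusted dimension scores) is out
  of scope: the classifier accepts only ratio cut-points. A user-supplied
  nomogram callable can be applied to the per-method BSA table produced by
  the worked-example mode.
* Mesh handling sums triangle areas unconditionally: self-intersecting or
  non-watertight avatars are not detected, matching how scan software
  totals its triangles but placing mesh QC out of scope.
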