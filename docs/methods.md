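# Methods

## The problem and the data model

After a colorectal resection with anastomosis, patients are monitored for an
anastomotic leak (AL), typically manifest between postoperative days (POD) 5
and 14. The question the package operationalises: how well do the 5-day
postoperative courses of CRP (mg/L), PCT (ng/mL) and WBC (×1000/mm³) — as
isolated daily values, as linear trajectories, and as binary day-to-day rise
rules — discriminate the patients who will leak?

Patient-level records from such studies are rarely deposited; what is
published are group-wise summaries: mean (SD) per (marker, day, outcome
group), the measurement schedule, and the outcome prevalence. The package
therefore carries a first-class synthetic-cohort generator whose default
parameters are those published summaries: CRP and PCT measured on day 0
(preoperative) and PODs 1–5, WBC on days 0, 1, 3, 5; AL prevalence 22/205
(10.7%), with an option to fix the split at exactly 22/183.

## Synthetic cohort generator

Each patient i receives a latent factor Z_i ~ N(0,1). The value at
(marker m, day d) for a patient in group g is

    v = μ(m,d,g) + σ(m,d,g) · (√ρ · Z_i + √(1−ρ) · ε),   ε ~ N(0,1) iid,

so every marginal is exactly N(μ, σ²) while any two measurements of one
patient correlate at ρ. Defaults: ρ = 0.3 — published summaries say nothing
about within-patient dependence, and 0.3 is a middling value for repeated
inflammatory markers; configurable in [0, 1). A lognormal family
(moment-matched per cell) is available because biomarker distributions are
right-skewed; Gaussian is the default since only two moments are published.
Negative draws are floored at 0 by default (concentrations are
non-negative); tests of Gaussian-moment properties disable the floor, since
with CRP POD-5 SD (65.57) larger than its mean (58.61) truncation moves the
mean by several Monte-Carlo standard errors.

What the generator does *not* emulate: within-patient smoothness beyond the
single shared factor (real trajectories are autocorrelated day to day, not
exchangeable), assay floors/ceilings, missing visits, and any link between a
patient's trajectory shape and the *timing* of the leak. Consequences worth
knowing: day-to-day deltas are noisier than real courses, so rise rules fire
often in both groups (their simulated specificity is pessimistic), and
trajectory-slope models look slightly better than on real data because group
separation grows linearly with day by construction. Passing tests therefore
validate the estimators and the pipeline, not clinical performance claims.

### Heteroscedastic power-law mode

For exercising the variability indices the generator can put a marker into a
mode where the per-patient (mean, SD) cloud follows SD = a·meanˣ: a level
m_i is drawn uniformly across the span of the group's day means, the target
SD a·m_iˣ receives a lognormal scatter (0.2 on the log scale — realistic
biological noise around the law), and the day values are a random
standardized pattern rescaled so the patient's sample mean and sample SD
equal m_i and the target exactly. Controlling the sample moments directly is
deliberate: with only 4–6 measurements per patient, iid draws make the
sample mean an error-laden proxy for the true level, and that
errors-in-variables noise attenuates any fitted exponent well below its
target — the cloud would not follow the law it is supposed to embody. The
within-patient correlation ρ is not applied in this mode.

## Trajectory features

The "trajectory" is the unweighted OLS slope of value on day index over the
observation window; consecutive-day deltas follow the actual schedule (for
WBC the pairs are 0→1, 1→3, 3→5 — no interpolation). The window defaults to
days 0–5 and can be restricted to PODs 1–5: the study conditions are
ambiguous about whether "day 0" enters the trend, so both are supported and
the choice is a config switch that propagates to the variability module.

Rise rules use strict inequality — an increase of *more than* the threshold
(50 mg/L CRP, 0.5 ng/mL PCT, 1.0 ×1000/mm³ WBC) between two consecutive
scheduled days; a delta exactly at the threshold does not trigger. Per-pair
flags are retained so a rule can be evaluated restricted to one day pair.

## Prediction and ROC analysis

Logistic models are maximum-likelihood fits (statsmodels' binomial GLM,
i.e. IRLS; convergence on log-likelihood change < 1e-8, ≤ 100 iterations).
Under perfect separation the MLE diverges; the fit returns the last capped
IRLS iterate flagged `converged=False` with a warning, and a small ridge
penalty (intercept excluded) is available as a stabiliser.

AUC is computed as the concordance probability from midranks (ties ½), which
equals the trapezoidal area under the empirical ROC curve exactly. Inference
uses DeLong's structural-components variance for the 95% CI (truncated to
[0, 1]) and the two-sided test against AUC = 0.5; Hanley–McNeil is available
for cross-checking. Cutoffs maximise Youden's J = SN + SP − 1 over midpoints
between adjacent distinct scores, with ties broken toward higher specificity
— the published tables print cutoffs without naming a criterion, and Youden
with a specificity-leaning tie-break matches their emphasis on specificity
and NPV. The criterion is a single function and is swappable.

Raw per-day predictors are scored by the marker value itself (so the cutoff
is in marker units); trajectory models and combinations are scored by the
logistic predicted probability (AUC is invariant to this monotone transform;
the cutoff lives on the risk scale). Binary rise rules are evaluated from
their 2×2 table; fed through the same concordance machinery their AUC is
(SN+SP)/2, the area under the single-point ROC, with the DeLong CI computed
on the 0/1 scores — the conventional summary for a binary test. PPV/NPV are
computed at the sample prevalence, with no external-prevalence adjustment.
No cross-validation or external validation is performed: the target of the
exercise is apparent performance.

## Variability indices

Per patient and marker: within-individual SD (n−1 denominator), CV =
SD/mean, and VIM = SD / meanˣ · cohort_meanˣ. The exponent x minimises
Σ(SD_i − a·mean_iˣ)² by nonlinear least squares (scipy `curve_fit`,
initialised from log–log OLS on the positive-SD points); it is estimated
once per marker on the pooled cohort — per-group exponents would build the
group difference into the index itself. The cohort mean is the mean of all
of the marker's measurements in the window. Patients need ≥ 3 measurements
(configurable): an SD from 2 points is legal but dominated by noise.

Group comparisons report the mean difference with a Welch-t 95% CI and a
tie-corrected asymptotic Mann–Whitney p-value; pairing a normal-theory CI
with a rank test mirrors the shape of published variability tables while
keeping the distribution-free test for significance.

VIM's defining property — decorrelation from the patient's level when the
power law holds — is asserted in tests (|r| < 0.1 at n = 2000, against
r > 0.5 for raw SD) and reported by the acceptance script.

## Study-design arithmetic

Minimum sample size uses the finite-population-corrected Cochran formula
n = ⌈N·q / ((N−1)e² + q)⌉ with q = z²p(1−p). With N = 420, e = 0.05, 95%
confidence and p = 0.5 this yields 201 (N = 410 gives 199, N = 400 gives
197); N defaults to 420, the top of the plausible 400–420 eligible-patient
range. Percentages round half-up to 1 decimal; sample sizes round up.

## Pipeline and reproducibility

`run_pipeline` is a pure function of (input data or simulation config, run
config, seed). The bundle contains the cohort, features, group-wise day
summaries with Mann–Whitney p-values (significance marked at p < 0.05, no
multiple-testing correction — deliberately mirroring how such single-centre
analyses are reported), ROC tables for isolated days / trajectories / rules,
variability tables, and a JSON manifest (config, seed, version). CSV floats
use a fixed `%.10g` format so identical runs are byte-identical.

## Problem sizes and numerical choices

Simulation-based checks use: 20 000 patients for moment recovery (mean
within 4σ/√n per cell), 50 000 for the binormal AUC consistency check
(within 0.005 of Φ(Δμ/√(σ₀²+σ₁²))), 5 000 for logistic parameter recovery
(within 3 SE), 2 000 for power-law exponent recovery (within 0.05) and for
null-cohort behaviour (all AUC within 0.08 of 0.5), and 205 — the study
scale — for report-shaped output. Ties in ranks are handled by midranks
throughout; degenerate inputs (single class, < 2 points, zero variance,
zero-denominator metrics) either raise typed errors or return NaN markers as
documented per function.

## Known limitations

- Marginal-moment simulation cannot reproduce the published real-data AUCs;
  simulated discrimination reflects the configured group separation plus the
  dependence model, and trajectory AUCs in particular run high.
- DeLong inference is asymptotic; with 22 events the CI is approximate
  (the bootstrap cross-check in the tests quantifies the agreement).
- The power-law fit is unweighted; heteroscedastic residuals around the law
  are ignored, as is standard for this index.
- The CLI covers the pipeline's surface, not every library option; the
  Python API is the primary interface.
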