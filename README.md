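# leaktraj

Anastomotic leak (AL) — dehiscence of the surgical joint after colorectal
resection — is the complication that keeps patients in hospital after
otherwise uneventful surgery. Inflammatory blood markers measured daily after
the operation carry an early signal: C-reactive protein (CRP, mg/L),
procalcitonin (PCT, ng/mL) and white-blood-cell count (WBC, ×1000/mm³).
`leaktraj` implements the full analytic chain a biomarker-trajectory study of
this question runs, as a tested, reusable Python library:

- **synthetic cohorts**: patient-level longitudinal data simulated from
  group-wise means/SDs per (marker, day), with a configurable
  within-patient correlation, the clinical measurement schedule (CRP/PCT
  daily on days 0–5, WBC on days 0, 1, 3, 5) and an AL prevalence of 22/205;
- **trajectory features**: per-patient OLS slope over the 5-day window,
  consecutive-day deltas, and binary *rise rules* (an increase of more than
  50 mg/L CRP, 0.5 ng/mL PCT or 1.0 ×1000/mm³ WBC between consecutive days);
- **prediction**: logistic models for single markers and combinations, AUC as
  the pairwise concordance P(score_AL > score_noAL) with ties ½, DeLong 95%
  CIs and p-values against the chance diagonal, Youden-optimal cutoffs
  (J = SN + SP − 1, ties broken toward specificity) and SN/SP/PPV/NPV;
- **variability indices**: within-patient SD, CV = SD/mean, and VIM =
  SD / meanˣ · cohort_meanˣ with x fitted by nonlinear regression of
  SD = a·meanˣ across patients, compared between groups by Mann–Whitney;
- **study design**: the finite-population (Cochran-corrected) minimum sample
  size n = ⌈N·z²p(1−p) / ((N−1)e² + z²p(1−p))⌉ and descriptive summaries;
- a **pipeline** (`run_pipeline` / the `leaktraj` CLI) that emits the whole
  report bundle deterministically from a config and a seed.

## Worked example

```python
import leaktraj as lt

cohort = lt.simulate_cohort(
    lt.table2_default_config(fixed_group_sizes=(22, 183), seed=3)
)
features = lt.compute_features(cohort)
specs = [
    lt.ModelSpec("PCT POD 5", "raw", ("PCT",), day=5),
    lt.ModelSpec("CRP+PCT+WBC trajectory", "trajectory", ("CRP", "PCT", "WBC")),
]
for s in lt.evaluate_marker_panel(cohort, features, specs):
    print(s.name, round(s.auc, 2), round(s.cutoff, 2), s.sn, s.npv)
```

On this seed the full panel (see `examples/roc_panel.py`) prints:

```
PCT POD 5                AUC 0.97 (0.93-1.00)  cutoff   4.33  SN  95.5%  SP  97.3%  NPV  99.4%
CRP POD 3                AUC 0.82 (0.71-0.94)  cutoff 115.66  SN  68.2%  SP  91.8%  NPV  96.0%
PCT trajectory           AUC 0.99 (0.98-1.00)  cutoff   0.06  SN 100.0%  SP  90.2%  NPV 100.0%
CRP+PCT+WBC trajectory   AUC 0.99 (0.98-1.00)  cutoff   0.47  SN  90.9%  SP  99.5%  NPV  98.9%
```

Read: the day-5 PCT value alone separates leak from no-leak patients with
AUC 0.97 at a cutoff of 4.33 ng/mL; the combined three-marker trajectory
model does at least as well, and the negative predictive values near 100%
are what would let a surgeon discharge a low-scoring patient early. (These
are apparent-performance numbers on one simulated 205-patient cohort; they
fluctuate seed to seed.)

The `examples/` directory holds one short script per capability
(simulation, trajectory features, ROC panel, variability indices, sample
size); each prints its numbers with a line on what they mean. The same
operations are reachable from the shell:

```sh
leaktraj simulate --seed 1 --out cohort.csv
leaktraj features --in cohort.csv --out features.csv
leaktraj roc --cohort cohort.csv --out report/
leaktraj variability --in cohort.csv --out report/
leaktraj samplesize --N 420 --margin 0.05
leaktraj run --out report/          # the whole bundle, deterministically
```

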