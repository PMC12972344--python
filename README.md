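# filab — a laboratory-based frailty index for elderly trauma cohorts

`filab` implements a deficit-accumulation frailty index (FI-Lab) built
entirely from routine admission blood work, for risk stratification of
elderly hip-fracture patients in settings where interview- or
performance-based frailty instruments are impractical.  It is aimed at
clinical epidemiologists and biostatisticians who want the whole pipeline —
reference-range coding, scoring, data-driven panel reduction and survival
evaluation — as tested, scriptable building blocks.

## The index

Each laboratory analyte is coded against its sex-specific reference rule:
`x_ij = 1` if patient *i*'s value of analyte *j* falls outside the normal
range (above or below), else `0`.  The index is the deficit fraction

```
FI_i = (Σ_j x_ij) / n_i ,
```

where `n_i` counts the analytes actually measured for patient *i* — missing
analytes shrink the denominator instead of being imputed.  Patients with
fewer than 70 % of the panel measured are excluded.  Two panels ship as
fixtures: the full 44-analyte admission panel and a reduced 21-analyte
panel.  The reduction is reproducible in code: per-analyte two-sided
Mann–Whitney tests of the coded deficits between one-year decedents and
survivors, Benjamini–Hochberg adjustment, then the significant analytes
plus the non-significant ones with the smallest adjusted p until the target
size is reached (a volcano-plot ranking).

Predictive performance is evaluated with Kaplan–Meier curves and the
log-rank test across six score groups (edges 0.1–0.5, right-closed), Cox
proportional hazards with group dummies adjusted for age and gender (Efron
ties, Wald CIs), and fixed-horizon ROC/AUC at 6 and 12 months computed via
the rank identity `AUC = U / (n_pos · n_neg)` with DeLong standard errors.

Because no public patient-level data exist for this setting, the package
includes a synthetic cohort generator (latent Beta frailty → logistic
deficit loadings → exponential proportional-hazards mortality) whose
ground truth makes every stage testable; see `docs/methods.md`.

## Worked example

```python
from filab import FrailtyLabModel, GeneratorConfig, generate_cohort

cohort, _ = generate_cohort(GeneratorConfig(seed=1))   # 235 synthetic patients
res = FrailtyLabModel(cohort).fit(selection={"target_size": 21})
print(res.summary())
```

```
Laboratory-based frailty index — fit summary
============================================================
panel: filab44_selected21   patients scored: 235   excluded: 0
score: mean 0.261  median 0.250  min 0.00  max 0.74
percentiles: 1st 0.05  5th 0.10  95th 0.43  99th 0.59
panel selection: 1 significant + 20 trending -> 21 analytes
log-rank across score groups: p = 0.000124
AUC @ 183 d: 0.6472 (SE 0.0435, 95% CI 0.5620-0.7324; 52 deaths / 183 survivors)
AUC @ 365 d: 0.6828 (SE 0.0356, 95% CI 0.6130-0.7526; 95 deaths / 140 survivors)
Cox PH terms @ 365 d (reference: group 1, male):
  group[2]   HR   1.036  95% CI 0.347-3.087  p 0.9501
  ...
  group[6]   HR   6.250  95% CI 1.743-22.419  p 0.0049
```

Reading this: the cohort's score distribution (mean 0.26, right tail to
0.74) is grouped into six bins; survival separates strongly across groups
(log-rank p ≈ 1e-4); the one-year AUC of 0.68 says a randomly chosen
decedent outranks a randomly chosen survivor 68 % of the time; and the
hazard of death in the highest score group (> 0.5) is about six times that
of the lowest, after adjusting for age and gender.  At n = 235 only one
analyte clears the multiplicity-adjusted bar, so most of the 21 selected
analytes enter as "trending" — the expected behaviour at this sample size.

The same pipeline is scriptable:

```
filab run-all --n 235 --seed 1 -o report/        # simulate → select → evaluate
filab score --cohort mydata.csv --panel filab21  # score your own cohort CSV
```

`FrailtyLabResults` also exposes `plot_km()`, `plot_roc()` and
`plot_volcano()`, plus the underlying tables (`scores`, `volcano`,
`per_parameter`, `cox[h].to_frame()`).

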