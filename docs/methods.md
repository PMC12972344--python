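# Methods

This note documents the statistical procedures `filab` implements, the
conventions chosen where a convention had to be chosen, what the synthetic
cohort generator does and does not emulate, and known limitations.

## Deficit coding

Every analyte has a per-sex normality rule, shipped as a CSV fixture:
two-sided reference intervals, or one-sided cutoffs printed as `< upper` /
`> lower`.  Conventions:

* **Boundary convention.** Two-sided intervals are *inclusive-normal*: a
  value exactly on `lower` or `upper` codes 0.  One-sided rules follow
  their printed strict relation: CRP `< 6` means 6.0 codes 1; eGFR `> 45`
  means 45 codes 1.  Whether boundary-equal values should be normal is not
  decidable from the printed ranges alone; this literal reading is a
  package convention and is pinned by tests so that flipping it is a
  visible, deliberate change.
* **eGFR.** Shipped as a `lower_only` rule at 45 ml/min for both sexes —
  the CKD-stage-3a boundary appropriate for a cohort aged ≥ 70 — rather
  than the standard 90 ml/min adult cutoff.  An `AgeOverride` mechanism
  exists so that a < 70 default of 90 can be configured; it is not active
  in the shipped fixtures because the intended cohorts are entirely ≥ 70.
* **Fixture quirks.** Two source-table rows (male GGT "55", male ALT "45")
  lack relation symbols and are encoded `upper_only` consistent with their
  female rows; HbA1c appears in both % and mmol/mol units and both rows are
  retained as distinct analytes so the full panel counts 44; INR and Quick
  value are algebraically related but both coded, as printed.  Each quirk
  carries a `note` in the fixture CSV.
* Units are fixed by the fixture; no unit conversion is attempted.

## The score

`FI = n_deficits / n_available` per patient.  Missing analytes reduce the
denominator (no imputation); a patient with fewer than 70 % of the active
panel measured is excluded from all downstream stages rather than scored.
The availability threshold is measured against whichever panel is being
scored (44 or 21) and is configurable.  Score groups use right-closed bins
at one-decimal edges — [0, 0.1], (0.1, 0.2], …, (0.5, 1] — so a score of
2/20 = 0.1 is group 1 and 0.105 is group 2.  Summary percentiles
(1/5/95/99) use linear interpolation between order statistics.

## Panel selection

Per analyte, the 0/1 deficit codes of one-year decedents and survivors are
compared with a two-sided Mann–Whitney U test.  Binary data are maximally
tied, which drives two implementation choices:

* **Exact small-sample p.** For combined n ≤ 20 the permutation
  distribution of U collapses onto the hypergeometric distribution of the
  deficit count in one group, so the exact two-sided p is a hypergeometric
  tail sum — equivalent to full enumeration of label permutations, and
  verified against brute-force enumeration in the tests.
* **Lattice-aware normal approximation.** For larger samples the
  tie-corrected normal approximation is used with a continuity correction
  of n/4 (half the lattice step of U, which moves in increments of n/2 for
  two-valued data) rather than the generic 0.5.  With the generic
  correction the approximation is badly anti-conservative near the center
  of the null distribution; with the lattice-aware correction it agrees
  with exact enumeration to within 0.02 at combined n = 20.

Raw p-values are adjusted across testable analytes with Benjamini–Hochberg
(default; Holm and Bonferroni selectable).  BH is the default because it is
the standard choice for many-parallel Mann–Whitney screens; the original
analysis software's adjustment method is not documented, so ranked results
should be compared on raw p-values when reproducing other work.  The
volcano x-axis is the decedent–survivor difference in deficit prevalence
(log-fold-change is ill-defined when a prevalence is 0).

Selection takes all adjusted-significant analytes (ascending adjusted p),
then fills to the target size with the non-significant analytes of smallest
adjusted p ("descending tendency towards significance").  Ties break
deterministically by (adjusted p, raw p, |effect| descending, analyte id).
Judgment-based inclusion criteria such as organ-system coverage are
deliberately not encoded as heuristics; they are expressed through
`force_include` / `force_exclude`, and applied overrides are reported.

## Survival evaluation

* **Kaplan–Meier / log-rank**: product-limit estimate per score group with
  administrative censoring at the horizon; unweighted k-sample log-rank
  with chi-square reference (via lifelines).  Zero events overall returns
  p = 1; a single populated group raises.  Empty groups are dropped.
* **Cox PH**: dummies for groups 2–6 against group 1, plus age (per year)
  and a female indicator (`gender[2]`; male is the reference level — a
  convention, as is the choice of group 1 as reference).  Efron tie
  handling (day-granularity times produce ties).  CIs are 95 % Wald on the
  log-hazard scale; profile-likelihood CIs are not offered because the
  underlying fitter has no fixed-coefficient profiling support and a
  second hand-rolled Cox implementation solely for CIs was judged
  disproportionate.  Group dummies with zero events and constant
  adjustment covariates are dropped with a warning (their partial
  likelihood has no finite maximum / singular information).
* **Fixed-horizon ROC**: death on or before the horizon (183 d for 6
  months, 365 d for 1 year; configurable) is the binary outcome; patients
  censored before the horizon are excluded and counted.  This binary
  treatment assumes near-complete follow-up to the horizon, which is the
  intended use case; time-dependent ROC is out of scope.  AUC uses the
  rank (Mann–Whitney) identity with midranks; SE is the DeLong estimator;
  the per-analyte table reports a normal-theory two-sided p against
  AUC = 0.5.  For a binary marker the AUC reduces to
  (sensitivity + specificity)/2, which the tests assert.

## Synthetic cohort generator

Per patient: latent frailty `f ~ Beta(2, 3.3)`; analyte *j*'s deficit
`~ Bernoulli(expit(logit(p0_j) + λ_j f))`; a continuous lab value drawn
uniformly inside the sex-specific normal region if the code is 0, and
uniformly in a band outside it if 1 (side chosen at random for two-sided
rules; band width 50 % of the interval width or cutoff, clipped at 0) —
constructed so recoding the values reproduces the codes *exactly*, which
is the strongest cross-module test; independent per-analyte missingness;
survival `T ~ Exponential(rate0 · exp(β · d̄))` with `d̄` the true deficit
fraction over the whole panel, censored administratively at 365 d.

Defaults (all config-exposed): n = 235 patients, age ~ N(83.65, 6.3²)
truncated at 70, 67 % female, baseline deficit prevalence 0.15, loading
λ = 2.5 on the 21 reduced-panel analytes (0 elsewhere), β = 4.0 per unit
deficit fraction, `rate0 = 5.0e-4`/day, missingness 2 % (70 % for
1.25-vitamin-D, cholinesterase and bone alkaline phosphatase, which are
rarely ordered at admission).  `rate0` was calibrated once, by simulation
at large n under these defaults, to the ~38 % one-year mortality the
generator is meant to emulate; the resulting score distribution (mean
≈ 0.3, 95th percentile ≈ 0.6, tail to ≈ 0.9) approximates the intended
shape without being a fitted quantity.  Per-analyte baseline prevalences
have no empirical anchor and should be treated as unvalidated.

A second generator, `generate_planted_cohort`, draws the one-year death
flag first and plants an exact deficit-prevalence difference (default
0.30) between decedents and survivors for a chosen analyte subset (default:
the first 13 reduced-panel analytes), with null analytes elsewhere and no
missingness.  It exists because the frailty-driven model controls
outcome–deficit association only indirectly; selection-stage studies need
the prevalence difference itself as the knob.

What the generator does **not** emulate: correlations between biologically
linked analytes (hemoglobin–hematocrit, INR–Quick) beyond the shared
frailty loading; age or sex effects on hazard (so adjusted Cox terms are
null in synthetic data); non-exponential baselines; informative
missingness; measurement error in the continuous values.  Passing tests on
synthetic cohorts therefore demonstrate the *correctness of the machinery*
(coding, arithmetic, test statistics, estimator calibration), not the
clinical validity of the index on real patients.

## Simulation sizes and numerical choices

Parameter-recovery checks run at n = 1,000 patients × 500 replicates (Cox
log-hazard bias and CI coverage) and n = 235 × 200 replicates (null-AUC
calibration); the round-trip coding check runs at n = 10,000.  These sizes
make Monte-Carlo error comfortably smaller than the tolerances being
asserted while keeping the default test run short.  Degenerate inputs are
errors, not silent answers: empty cohorts, degenerate outcomes (all died /
all survived), single populated score groups, and ROC horizons with no
positives or no negatives all raise with a named cause; all-missing
deficit vectors are flagged excluded rather than divided by zero.
Constant analytes get AUC exactly 0.5 (all ties) and are flagged
untestable.

## Limitations

The reduced 21-analyte panel shipped as a fixture reflects one specific
hospital's reference ranges and assay set; other laboratories must supply
their own panel CSV.  The selection stage reproduces the *procedure*, not
the original cohort's outcome (which depended on private data).  The Cox
evaluation assumes proportional hazards across score groups and handles
neither competing risks nor time-varying covariates.
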