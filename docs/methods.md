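# Methods

This note documents the models, conventions and numerical choices
behind `abpmkit`, and what the simulation-based tests do and do not
demonstrate.

## ABPM summarisation

A recording is a strictly time-ordered sequence of systolic/diastolic
readings spanning at most 26 h, each carrying a device validity flag.
Parsing never drops rows: physiologically implausible readings
(SBP ≤ DBP, DBP < 40 mmHg, SBP > 300 mmHg) are flagged invalid with a
warning, and all statistics are computed over valid readings only.
Day and night windows are half-open on the clock — [06:00, 22:00) and
[22:00, 06:00) by default — so a reading stamped exactly 06:00 is
daytime and 22:00 night-time.

Validity follows the usual acquisition rules: at least 70 % of
recorded readings valid, ≥ 20 valid daytime readings with at least two
in every daytime clock hour, ≥ 7 valid night-time readings with at
least one per night hour. The per-hour clause is interpreted
literally per clock-hour bin (only for hours the recording actually
reaches); a lenient mode (`strict_per_hour: false`) checks the
aggregate counts only.

Summary conventions:

* **Means** are unweighted arithmetic means over valid readings in the
  window.
* **Loads** are the percentage of valid readings at or above the same
  window-specific hypertension cut-offs used for diagnosis (day
  135/85, night 120/70, 24-h 130/80 mmHg, inclusive). The load
  definition is a convention, chosen for consistency with the
  diagnostic thresholds.
* **Nocturnal reduction** is `100·(day mean − night mean)/day mean`;
  dipping is categorised from the systolic reduction at the standard
  cut-points: ≥ 20 % extreme dipper, 10–20 % dipper, 0–10 %
  non-dipper, < 0 % reverse dipper.
* **ARV** is the unweighted mean of absolute consecutive differences
  over valid readings, as the index is defined; a time-interval-
  weighted variant is available behind a flag because the day/night
  sampling intervals differ. The headline ARV is systolic (its
  magnitude, ~12–14 mmHg, is systolic-scale); diastolic ARV is also
  reported.
* **AASI** uses the OLS slope of DBP on SBP over all valid 24-h
  readings. It is undefined (NaN with a warning) for constant-SBP
  recordings.
* **PPI** defaults to the per-reading ratio averaged over the window,
  which is robust to window imbalance; the ratio-of-24-h-means variant
  is selectable. Neither variant can be reconciled with every
  published group summary of PPI alongside the same groups' SBP/DBP
  means — the per-reading definition is taken as canonical and the
  tension documented here rather than hidden.

Ambulatory hypertension is called when any window mean meets its
cut-off (inclusive, systolic or diastolic component).

## Organ-damage rules

Thresholds follow the clinical wording exactly: "exceeds" is a strict
`>` (LVMI 115/95 g/m², RWT 0.43, ACR 30 mg/g), "below" a strict `<`
(eGFR 60). LV mass uses the Devereux cube formula and body surface
area the Mosteller formula (Du Bois selectable); neither is dictated
by the rule set, both are stated so results are reproducible.
eGFR uses the 2009 CKD-EPI creatinine equation without the race
coefficient (the 2021 refit is selectable); the equation is continuous
at the sex-specific creatinine knot, which is tested.

Diastolic dysfunction: grade I iff E/A < 0.8. For E/A ≥ 0.8, grade
II (0.8–2.0, inclusive) or III (> 2.0) requires at least two positive
elevated-pressure markers among E/e′ > 14, LAVI > 34 mL/m²,
TRV > 2.8 m/s, septal e′ < 7 cm/s and lateral e′ < 10 cm/s, with the
e′ criteria counting only when TRV or LAVI is also positive (they are
supportive, not sufficient). The two-marker majority is a
guideline-style choice; the exact count is not fixed by the rule text.
When missing markers could still change the call the grade is
`indeterminate`, never silently negative.

Cardiac damage is LVH **or** diastolic dysfunction of any grade
(including isolated grade I) — the inclusive reading of "hypertensive
cardiomyopathy". The composite is the disjunction over evaluable
organs; a missing organ propagates as indeterminate with a warning and
is excluded, never treated as healthy.

## The synthetic cohort

The generator exists so every stage is testable without patient data.
It emulates second-order structure only — no baroreflex, posture or
activity covariates.

**Recording model.** SBP is a two-level circadian profile (day/night
window means) plus stationary AR(1) noise (per-step coefficient
φ = 0.5 by default). Two quantities are calibrated analytically:

1. *ARV*: with `s` the standard deviation of consecutive noise
   differences (`s² = 2σ²/(1+φ)` for innovation sd σ), the expected
   ARV is the average over gaps of the folded-normal mean
   `E|Δlevel + N(0, s²)|`, which includes the two day↔night level
   jumps. `s` is solved by root finding so this expectation equals
   the target; a target below the jump-only floor is rejected as
   infeasible.
2. *AASI*: the 24-h OLS slope of DBP on SBP decomposes into the
   within-window slope `b_w` and a between-window term from the
   circadian co-variation of the day/night levels. Given the target
   total slope `1 − AASI*`, `b_w` is solved from
   `b_total = (b_w·V_within + Cov_between) / (V_within + Var_between)`.
   DBP is then `level_D + b_w·e + η` with η the residual diastolic
   scatter (default sd 4 mmHg, a realism choice that does not bias the
   slope).

Readings are removed independently at the requested missingness
(uniform at random — no informative-missingness mechanism is claimed).
Monte-Carlo tests show the ARV and AASI estimators recover their
targets to within ~1 % in expectation at the 64-reading schedule;
the acceptance suite checks 5 % over 200 seeds at the two group
profiles (ARV 11.93 and 14.08 mmHg, AASI 0.58 and 0.69). Densifying
the schedule leaves the AASI expectation unchanged and shrinks the ARV
estimator's variance (the calibration is re-solved per schedule).

**Cohort model.** Two groups (default 39 damaged / 40 controls) with
separations injected only where the study design expects them: the
three indices (group means/SDs as above and PPI 58.54 ± 11.34 vs
48.07 ± 6.68), BMI, sex prevalence and the renal markers; age, HbA1c,
smoking and all circadian BP levels are null by construction, so
downstream false-positive rates can be checked at the nominal level.
Variables reported as median (IQR) in skewed clinical tables are
generated log-normally with parameters matched by quantile; symmetric
variables normally. Each subject's DBP window means are derived from
the subject's PPI target (`DBP = SBP·(1 − PPI/100)`); this makes the
simulated diastolic levels lower than typical clinical values — a
deliberate resolution of the inconsistency noted above in favour of
the index under study, documented rather than averaged away.

Damaged subjects receive an organ combination drawn from the observed
frequency mix (heart-only ≈ 49 %, kidney-only ≈ 26 %, …) and their
echo/lab values are sampled conditional on that assignment so the
rule-based classifier recovers the generated labels exactly; controls
are sampled strictly inside the healthy region of every rule. This is
what makes the end-to-end pipeline deterministic to test, and it is
also what passing tests do *not* show: real cohorts have borderline
subjects, correlated indices and measurement error in the rule inputs,
so real-data classification and regression results will be noisier
than the simulation suggests.

## Statistics

* Normality gate: two-sided one-sample Kolmogorov–Smirnov against the
  group's fitted normal (no small-sample correction), α = 0.05; the
  Lilliefors-corrected variant is selectable. t-tests assume equal
  variances; chi-square is uncorrected by default (Yates selectable).
* 2×2 odds ratios: cross-product with Wald log interval using
  z = 1.959964; Haldane–Anscombe 0.5 correction on zero cells, with a
  warning.
* Logistic models: maximum likelihood (statsmodels); numeric
  predictors are z-standardised on the whole sample, so continuous
  odds ratios are per SD and labelled as such. Separation is detected
  (non-convergence or |coefficient| > 30 on the standardised scale)
  and reported as an error, never silently penalised. The p < 0.25
  univariable screen plus a configurable clinically-forced set selects
  the multivariable model.
* Hosmer–Lemeshow uses 10 equal-frequency risk groups with g − 2
  degrees of freedom; Nagelkerke R² rescales Cox–Snell.
* Collinearity: pairwise Pearson r, tolerance/VIF from auxiliary
  regressions, condition number of the standardised design with
  intercept; influence via standardised Pearson residuals (flag at
  |r| ≥ 3.29) and Cook's distance (flag at 0.5) from the binomial GLM.
* ROC: rank/midrank AUC (identical to the normalised Mann–Whitney U,
  which is asserted as an invariant), DeLong variance for the CI and
  the test against AUC = 0.5, and a Youden-optimal cut-off over
  midpoint thresholds (score ≥ cutoff calls a case), ties broken
  toward higher specificity. The fast path equals exhaustive
  threshold search, which is tested.
* Cohen's kappa is the closed form with marginal-product expected
  agreement.

## Problem sizes in the test suite

The simulation-heavy checks run at sizes chosen to make their
conclusions meaningful while keeping the suite quick to iterate on:
generator recovery over 200 seeds per profile, pipeline power and
null-rate checks over 200 cohort replicates at the study size, and
Wald-interval coverage over 1,000 fits at n = 150. The acceptance
script uses 60 cohort replicates for the AUC and significance-rate
summaries.

## Known limitations

* The AR(1)+two-level recording model reproduces means, ARV and AASI
  but not morning surges, activity-driven variance or measurement
  artefacts.
* AASI calibration is exact in expectation only; the finite-sample OLS
  ratio has O(1/n) bias, negligible at 64 readings.
* The multivariable model can genuinely separate at small n with the
  default effect sizes; the pipeline reports this and omits the model
  rather than fitting a penalised alternative.
* No survival, longitudinal or multiple-imputation machinery; no
  power/sample-size calculator.
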