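# Methods

This note records the models and procedures implemented in `mibgquant`,
the defaults that matter, the design choices made where the design was
genuinely open, and what the synthetic generators do and do not emulate.

## Planar quantification

The heart-to-mediastinum ratio is the mean counts/pixel inside a polygonal
heart ROI divided by the mean counts/pixel inside a 7×7-pixel mediastinal
reference square, computed separately on the early (~15 min) and late
(~4 h) anterior planar images. Myocardial washout is

    WO = 100 × {(He − Me) − (Hl − Ml) × k} / (He − Me)   [%]

with `k` the physical-decay correction of the late acquisition. The default
`k = 1.21` is the conventional constant for a 3 h 45 min interval;
`planar.decay_factor(interval_hours, half_life_hours=13.22)` recomputes
`2^(Δt/T½)` for other protocols (for 3.75 h it gives 1.2173, which the
conventional constant truncates to two decimals). The constant is the
default for fidelity to common practice; recomputation is opt-in.

Numerical choices:

* **Rasterization.** A polygon selects the pixels whose centers fall inside
  it (even-odd rule). Centers exactly on the boundary resolve half-open:
  left/top edges in, right/bottom out, implemented by nudging the test
  point by 10⁻⁹ pixel down-right. This makes masks deterministic and
  complementary polygons non-overlapping.
* **`He ≤ Me` is an error**, not `WO = 0`: the formula is undefined there,
  and silent coercion would hide phantom or ROI bugs.
* Counts are stored as integers; all derived statistics are floats.
* `auto_mediastinal_roi` automates the manual placement rule "upper
  mediastinum, below the thyroid": it scans 7×7 windows in the upper half
  of the image restricted to the middle third of columns and returns the
  window with minimal mean counts, tie-broken topmost-then-leftmost, never
  touching a 1-pixel border margin. It assumes the mediastinal gap is the
  coldest upper-midline structure, which holds for the phantoms and for
  typical anterior thoracic views, but callers can always supply the ROI.

One `RoiSet` is used per time point; if the late set is omitted the early
set is propagated (whether clinical readers redraw or propagate is
protocol-dependent; both are supported).

## SPECT 17-segment scoring

Short-axis volumes are mapped to the standard AHA division of the left
ventricle: 6 basal, 6 mid-cavity and 4 apical angular sectors plus the
apex. The anterior wall is at 12 o'clock, numbering proceeds
counter-clockwise in the standard display (septum on the left); basal/mid
sectors are 60°, apical sectors 90°, each centered on its wall. Slices are
partitioned apex-to-base: the apex cap takes `max(1, n//6)` slices, the
remainder splits into three near-equal blocks (apical, mid, basal).
Myocardial voxels are selected by a radial annulus around the per-slice
long-axis center (solid disk at the apex); no edge-detection segmentation
is attempted because volumes here are synthetic or pre-segmented.

Per-segment mean counts are expressed as a percentage of the maximum
segment (so quantification is invariant to global count scaling) and scored
on the 5-point scale after rounding half-up to an integer percent:
≥70 → 0, 60–69 → 1, 50–59 → 2, 40–49 → 3, ≤39 → 4. Read literally, the
clinical bin labels ("greater than 70 % normal", "69–60 %", …, "lower than
39 %") leave exactly 70 and the 39/40 boundary ambiguous; the default makes
the bins contiguous (70 → 0, 39 → 4). The `strict_gt70` switch restores the
strict reading, under which an exact 70 falls into the mild bin.

ESS and LSS are the sums of the 17 early and late segment scores
(range 0–68); DSS = ESS − LSS in exact integer arithmetic, so a cohort
whose late defects exceed the early ones has a negative mean DSS.

Visual scoring is replaced by deterministic computation on uptake
percentages. Observer variability is *modelled*, not elicited:
`multi_reader_scores` perturbs the computed uptake with per-reader
bias/noise (percentage points, clipped to [0, 100]) before scoring, which
feeds the ICC analysis. Passing reader-agreement tests therefore shows the
agreement statistics behave correctly, not that human readers agree.

## Endpoint adjudication and statistics

The composite arrhythmic endpoint (AE) is any of: sustained ventricular
tachycardia (>30 s), resuscitated cardiac arrest, appropriate ICD therapy
(anti-tachycardial pacing or defibrillation), or sudden cardiac death. The
secondary endpoint is appropriate ICD therapy alone. Event time is the
event month; otherwise the record is censored at the end of follow-up
(also for the secondary endpoint when a non-ICD event occurred). A tie
between event and censoring time counts as an event.

* **Group comparisons**: χ² without continuity correction when all expected
  cell counts are ≥5, Fisher's exact test for sparse 2×2 tables; for
  continuous variables, Student's t-test when Shapiro-Wilk accepts
  normality in both groups at α = .05, else Mann-Whitney U. The normality
  gate makes the informal "when appropriate" rule explicit and auditable.
* **Survival**: Kaplan-Meier product-limit curves (lifelines). Cox models
  are partial-likelihood fits; the model χ² is the likelihood-ratio
  statistic against the null model, and in sequential mode each
  covariate's change-χ² is twice the partial-log-likelihood gain over the
  model with the preceding covariates, in the caller-given order (no
  automatic stepwise selection). Proportionality is checked with the
  scaled-residual trend test (rank time transform); a violation at α = .05
  flags the fit but does not abort it.
* **Time-dependent ROC** uses the cumulative-case / dynamic-control
  definition with Kaplan-Meier estimates inside the marker strata:
  `Se(c) = [1 − S(t|X>c)]·P(X>c)/[1 − S(t)]`,
  `Sp(c) = S(t|X≤c)·P(X≤c)/S(t)`. Without censoring this reduces *exactly*
  to the empirical ROC, which the tests verify against an independent ROC
  implementation. The AUC integrates the (FPR, TPR) staircase by the
  trapezoid rule with lexicographically ordered, tie-quantized sort keys so
  float noise in the KM products cannot distort the path. The estimator is
  not forced monotone; on small samples isolated non-monotone points can
  occur, as is characteristic of this estimator.
* **Late-H/M categories**: <1.2 low, >1.6 high, the closed interval
  [1.2, 1.6] intermediate (the outer bins are defined by strict
  inequalities, so the boundary values belong to the intermediate bin).
  The bell-shape test pools the two extreme bins and compares the pooled
  group against the intermediate bin on the endpoint with a 2×2 χ²; this
  combined-extremes design is used because the low bin is typically too
  small for a three-group test.
* **ICC**: two-way random-effects, absolute-agreement, single-rater
  ICC(2,1) with an F-based 95% CI (pingouin), labelled with the clinical
  bands <.40 poor, .40–.59 fair, .60–.74 good, .75–1.00 excellent. The
  consistency form can be obtained from the same ANOVA but the
  absolute-agreement form is the default because reader *level* differences
  matter for summed scores. Zero between-subject variance is an error (the
  ratio is undefined), as are <2 readers, <5 subjects, or missing cells.

## Synthetic generators

**Planar phantom.** An elliptical "heart" in the lower mid-field, a cold
mediastinal band in the upper midline and a lung-like background at
`M + 0.25·|H − M|` counts/pixel. Noiseless images paint the rounded true
means (exact recovery for integer truths); noisy images are Poisson with
the true means as expectations, so the H/M estimator's standard error
follows counting statistics (delta method), which the coverage tests use.
Not emulated: attenuation, scatter, collimator response, liver/lung
overlap, patient motion — so passing tests show estimator correctness
under ideal counting noise, not robustness to clinical confounders.

**SPECT phantom.** An annular wall painted sector-by-sector at
`peak_counts × uptake/100` (default peak 500 counts/voxel, 32×64×64
volume, wall radii 8–13 voxels, slices 4–27), optional Poisson noise. The
generator returns the voxel-label volume so tests can average counts over
the generating masks as an oracle independent of the quantification path.
Tomographic reconstruction, pre-filtering and camera physics are out of
scope; volumes are born in short-axis orientation.

**Cohort.** Continuous covariates (age, BMI, LVEF, early/late H/M, WO,
ESS, LSS) come from a Gaussian copula whose marginals default to the
published baseline table of the 170-patient chronic-heart-failure ICD
cohort the generator emulates; the printed BMI row (1.73 ± 0.59 kg/m²) is
kept verbatim for table fidelity even though the printed unit is
implausible for a BMI. Default cross-correlations are 0 except
ESS↔LSS = +0.8 and late H/M↔ESS = −0.4 — clinically plausible placeholders
(early and late defect burdens track each other; worse innervation means
lower H/M and higher scores), configurable, and not claims about the
source data, which reports only marginals. Out-of-range draws are redrawn
(not clipped) against physical bounds so means are preserved to first
order; ESS/LSS are then rounded to integers in [0, 68]. Binary covariates
are Bernoulli at the published prevalences.

The event process is exponential with per-patient rate

    h_i = h0 · exp(β·ESS_i) · m(cat(late H/M_i)),

defaults `β = log(1.028)` (the published adjusted hazard ratio per ESS
point), category multipliers (1.0, 2.0, 1.0) for (low, intermediate,
high) — a piecewise encoding of the bell-shaped risk pattern, chosen
because only the categorical pattern, not a functional form, is reported —
and `h0 = 0.0056 /month`, set so that with the default covariate mix and
uniform censoring over 1–51 months (the published follow-up range) about
40 % of patients experience an event, matching the 69/170 observed.
Event types are multinomial at the published breakdown (25, 22, 8, 14 of
69). Because the copula correlates late H/M with ESS and the hazard
contains the late-H/M category, a univariate Cox on ESS is confounded *by
construction*; parameter-recovery checks therefore fit the generating
model (ESS + intermediate-category indicator). All generators are
byte-reproducible for a fixed seed.

## Pipeline and formats

Cohorts travel as UTF-8 comma-separated CSV with a header row, empty
fields for missing values, months as decimal floats and 0-based row-major
pixel coordinates everywhere. Columns: `id`, demographics/comorbidities
(`age`, `sex_male`, `bmi`, `lvef`, `nyha_class` ∈ {2,3}, `ischemic`,
`lbbb`, `diabetes`, `hypertension`, `smoker`, `dyslipidemia`), medications
(`med_acei`, `med_arb`, `med_mra`, `med_beta_blocker`, `med_amiodarone`,
`med_statin`, `med_diuretic`), `prevention` ∈ {primary, secondary},
imaging (`early_hm`, `late_hm`, `wo_percent`, `ess`, `lss`, `dss`) and
follow-up (`followup_months`, `event_type`, `event_month`). Images write
to DICOM secondary capture (single- and multi-frame, UIDs derived from the
content hash so identical images give identical bytes) and to a `.npy` +
JSON-sidecar container; ROI sets and LV geometry serialize as JSON.

`run_pipeline` executes simulate → quantify → analyze from a single
validated `RunConfig` (unknown keys and covariate names are rejected
before any computation); every output carries the config hash and seed,
and identical config+seed yields byte-identical CSV/JSON bundles. The
demo quantification stage derives its planar truth from the calibrated
cohort means (mediastinum fixed at 100 counts/pixel, the late pair solved
so that both the late H/M and the washout hit their calibrated means).

## Problem sizes and known limitations

Default verification sizes were chosen to keep Monte-Carlo error well below
the tolerances they check: law-of-large-numbers calibration at n = 10 000
(3 SE), Cox parameter recovery at n = 20 000 × 50 replicates (≥90 % CI
coverage), planar Poisson coverage over 200 seeds, ICC closed-form
comparison at 500 subjects × 3 readers (tolerance 0.02).

Known limitations: no competing-risks handling (non-arrhythmic deaths are
censored); no collimator standardization of H/M beyond the decay-factor
hook; the 17-segment mapping assumes a circular annulus per slice and a
straight long axis; the synthetic cohort cannot reproduce the published
regression coefficients on n = 170 (only recovery of the generating
parameters at large n is claimed); and the bell-shape hazard multipliers
are a modelling device, not an estimate.
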