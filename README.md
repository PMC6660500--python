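# mibgquant

Quantification and outcome analysis for cardiac sympathetic-innervation
scintigraphy with ¹²³I-*m*IBG, a radiolabeled norepinephrine analogue taken
up by presynaptic cardiac sympathetic nerve endings. In chronic heart
failure, impaired cardiac ¹²³I-mIBG uptake carries prognostic information
for arrhythmic events (sustained ventricular tachycardia, resuscitated
cardiac arrest, appropriate ICD therapy, sudden cardiac death), which is why
these images are quantified in patients evaluated for an implantable
cardioverter-defibrillator (ICD).

The package is aimed at nuclear-cardiology and biostatistics researchers who
need the full measurement-to-outcome chain as reusable, tested code:

* **planar** — heart-to-mediastinum (H/M) count-density ratios from a
  polygonal heart ROI and a 7×7-pixel mediastinal reference square, and the
  background- and decay-corrected myocardial washout

  ```
  WO = 100 × {(He − Me) − (Hl − Ml) × 1.21} / (He − Me)   [%]
  ```

  where `H`/`M` are mean counts/pixel in the heart/mediastinal ROI, `e`/`l`
  the early (~15 min) and late (~4 h) acquisitions, and 1.21 the ¹²³I
  physical-decay correction for the 3 h 45 min interval
  (`2^(Δt/T½)`, `T½ = 13.22 h`).

* **spect** — AHA 17-segment mapping of short-axis volumes (6 basal, 6 mid,
  4 apical sectors + apex), per-segment uptake as % of maximum, the 5-point
  defect score per segment (≥70 % → 0 … ≤39 % → 4), and the summed scores
  ESS, LSS and DSS = ESS − LSS, plus a multi-reader perturbation model for
  inter-observer studies.

* **stats** — composite-endpoint adjudication, two-group comparisons
  (t / Mann-Whitney / χ²), Kaplan-Meier curves, uni-/multivariable Cox
  models with sequential change-χ² and a proportional-hazards residual
  check, time-dependent ROC for censored data by the Kaplan-Meier method,
  late-H/M categorization (<1.2 / 1.2–1.6 / >1.6) with the combined-extremes
  "bell-shape" test, and ICC(2,1) with the clinical agreement bands
  (<.40 poor, .40–.59 fair, .60–.74 good, ≥.75 excellent).

* **phantom** — synthetic planar pairs, short-axis volumes and a survival
  cohort with known ground truth; the cohort calibration reproduces the
  covariate and imaging-metric distributions of a published 170-patient
  chronic-heart-failure ICD cohort and encodes a log-linear ESS hazard
  (HR 1.028 per point) plus a bell-shaped late-H/M category effect.

* **io / pipeline / cli** — DICOM (secondary capture, single- and
  multi-frame), plain array containers, ROI JSON, cohort CSV, and the
  `mibgquant` command-line driver tying simulate → quantify → analyze into
  one seeded, byte-reproducible run.

## Worked example

```python
import numpy as np
from mibgquant import planar, spect, stats
from mibgquant.phantom import PlanarTruth, make_planar_pair, make_cohort

# planar: a noiseless phantom with true He=162, Me=100, Hl=121, Ml=60
pair = make_planar_pair(PlanarTruth(he=162, me=100, hl=121, ml=60))
m = planar.compute_metrics(pair.early, pair.late, pair.rois)
print(m.early_hm, round(m.wo_percent, 1))    # 1.62 -19.0

# cohort: simulate the calibrated study population and fit the Cox model
df = stats.adjudicate(make_cohort(seed=1, n=170))
print(len(df), int(df.ae_flag.sum()))        # 170 71
fit = stats.cox_fit(df, "ae_time", "ae_flag", ["ess"], sequential=True)
print(round(fit.hr("ess"), 3), [round(x, 3) for x in fit.ci("ess")])
# 1.032 [1.011, 1.053]
```

The early H/M of 1.62 is the generating ratio 162/100 recovered exactly;
the negative washout says this particular phantom's background-corrected
heart counts *grew* between time points after decay correction
(100×(62 − 61×1.21)/62 ≈ −19.0 %). In the simulated cohort, 71 of 170
patients reach the composite arrhythmic endpoint and the Cox hazard ratio
per ESS point (1.032, 95 % CI 1.011–1.053) recovers the generating value of
1.028.

The same run through the umbrella pipeline:

```sh
mibgquant run --seed 1 --out results/
```

writes `cohort.csv`, a baseline-characteristics table (`table1.csv`), the
Cox summary (`cox.csv`) and `results.json`; with seed 1 the bundle reports
mean early H/M 1.616, late-H/M category counts 10/103/57
(low/intermediate/high), a 24-month time-dependent ROC AUC of 0.62 for ESS
and a combined-extremes χ² p of 0.057.

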