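# Methods

## Scores

**LSVR.** The liver segmental volume ratio is the volume of Couinaud
segments I–III divided by the volume of segments IV–VIII, both in ml.
It is dimensionless, scale-invariant (doubling all volumes leaves it
unchanged) and kept at full floating precision internally; the 2-decimal
values seen in reports are a formatting choice only.

**LVCA.** The liver vein to cava attenuation score compares the mean
density of up to three hepatic veins (HU, measured near the venous
confluence) with the density of the inferior vena cava. With
`d = mean(vein HU) − IVC HU` and tolerance `t = 20 HU`:

| condition | score | meaning |
|---|---|---|
| veins not contrasted | 4 | no visible venous enhancement |
| `d < −t` | 3 | hypoattenuating |
| `|d| ≤ t` | 2 | isoattenuating |
| `d > t` | 1 | hyperattenuating |

Conventions: the boundary `|d| = t` counts as isoattenuating (the
tolerance is read inclusively); category 4 is driven by an explicit
`veins_contrasted` flag because "no visible contrast" is a visual call
with no numeric threshold — the measurement layer (or phantom
generator) must supply it. Fewer than three vein readings are averaged
with equal weights and logged as a warning rather than rejected, since
hepatic venous anatomy varies. The classifier is invariant to vein
ordering and to adding a constant to all HU values, and is a monotone
step function of the mean vein density with transitions exactly at
`IVC − t` and `IVC + t`.

**LSVAR.** The composite is the plain product `LSVR × LVCA`, so
`LSVR ≤ LSVAR ≤ 4·LSVR` always, with equality on the left exactly when
LVCA = 1.

## Phantom imaging

A `LabeledVolume` is a 3D HU grid plus a same-shape integer label grid
with a fixed, versioned code table (1–8 = Couinaud I–VIII, 10 = spleen,
20 = hepatic veins, 21 = IVC, 0 = background) and per-axis voxel
spacing in mm. Volumetry is voxel counting times voxel volume; ROI
attenuation is the arithmetic mean HU over a labeled region. Real
segmentation is out of scope — label maps are given or synthesized.

The generator partitions the grid with a demand-balanced binary space
partition and carves each region as the N voxels nearest a jittered
center inside its convex box, which guarantees connected,
non-overlapping blobs with *exact* voxel counts; measured volumes
therefore match targets to within single-voxel rounding, far inside
the 1–2% round-trip tolerances used in tests. HU values are the
specified region means plus additive Gaussian noise (default σ = 3 HU,
clipped to [−1024, 3071]); σ is kept below a quarter of the ±20 HU
LVCA tolerance so region means recover the intended category exactly.
Everything is deterministic for a fixed seed.

Defaults are a 96³ grid at 2 mm isotropic spacing (≈ 7 L capacity,
~0.3 s per phantom); tests use 64³ at 2.5 mm. Generation refuses specs
above 85% grid occupancy, where box granularity can no longer place
the regions. Semantic simplifications: one vein region stands for all
three hepatic veins (so the measured vein reading is a single value),
there is no confluence geometry, no anatomy-shaped organs, no contrast
kinetics, and no DICOM support. Phantoms round-trip to NIfTI pairs
(HU + labels with identical affines) plus a JSON code-table sidecar.

## Synthetic cohort

The generator emulates a 141-patient screening population: stiffness
strata of 90/20/12/5/4/10 patients over the bands <2.5, 2.5–2.9,
2.9–3.5, 3.5–4, 4–5, ≥5 kPa, giving 122 patients below and 19 at or
above the 3.5 kPa fibrosis threshold. Sampling is stratified — group
sizes are exact, never binomial. Stiffness is uniform within a band;
the open top band uses a shifted exponential (scale 1 kPa) capped at
8 kPa, about the ceiling seen in severe cirrhosis with gradient-echo
MRE.

Only medians and IQRs of the measurements are published, not
distributions, so families had to be chosen. Volumes are log-normal —
strictly positive and right-skewed, the standard choice for organ
volumes — with the configured group medians as scale parameters
(log-normal median = scale, so targets are medians by construction)
and log-sd calibrated from the printed IQRs via
`σ = ln(q3/q1)/(2·0.6745)`: negative group 333/1237/229 ml for
segments I–III, IV–VIII and spleen (σ 0.31/0.20/0.42), positive group
449/1160/442 ml (σ 0.43/0.33/0.52).

The LVCA is generated *through the classifier*, not sampled: a latent
category (negative-group mix 0.60/0.30/0.08/0.02, positive
0.05/0.10/0.25/0.60, chosen so the induced medians are 1 and 4 with
IQRs bracketing [1–2] and [3–4]) sets a vein–IVC density difference
drawn away from the ±20 HU boundary (category margins ≥ 5 HU against
the 2 HU per-vein jitter), an IVC density ~N(100, 5) HU, and the
contrasted flag (False iff category 4). Re-classifying the stored HU
values always reproduces the intended category, which keeps
`classify_lvca` on the tested path.

Stiffness–score dependence is induced only through group membership —
the weakest structure consistent with the published group statistics.
Consequences worth knowing: within-group correlations between scores
and stiffness are zero, there is no etiology mix, no biopsy grades,
and no CT–MRE time-interval effect. Passing tests show the analysis
chain is correct under these conditions, not that the scores would
achieve the same accuracy on real patients. Seven negative-group
patients get a missing splenic volume (emulating scans that do not
cover the whole spleen); the pipeline excludes them from the
splenic-volume ROC only. Clinical covariates (age, sex, BMI, AST, GGT,
APRI) are group-shifted pass-through fields for the generic group
comparisons; nothing downstream depends on them.

Under these defaults the composite LSVAR separates the groups far
better than the LSVR alone (the attenuation term contributes most of
the signal), and the test suite asserts this as a stochastic property
across 200 simulated cohorts rather than as a point value, since a
single synthetic cohort's AUC fluctuates with only 19 positives.

## Diagnostic statistics

* **ROC/AUC.** Thresholds are the unique observed scores plus an
  infinite sentinel; positivity is `score ≥ threshold`. The AUC is
  computed both as the trapezoidal area of the empirical ROC polygon
  (score ties give diagonal segments) and as the Mann–Whitney pair
  statistic with ties counted ½; the two are asserted equal to 1e-12
  on every call — an exact identity for the empirical curve, so any
  disagreement flags a defect. Both routes are additionally tested
  against an O(n²) brute-force oracle and scikit-learn.
* **AUC 95% CI.** DeLong's placement-based variance with a normal
  interval clipped to [0, 1] (verified against R's pROC to 4
  decimals); a seedable stratified percentile bootstrap (2000
  replicates) is available as an alternative. With fewer than two
  subjects in a class the DeLong variance is undefined; the standalone
  function raises, while the ROC constructor degrades to the
  uninformative interval [0, 1].
* **Youden cutoff.** Maximizes J = sensitivity + specificity − 1 over
  the observed thresholds; ties (within 1e-12, absorbing last-ulp
  differences between algebraically equal J values) break toward the
  smallest threshold, i.e. toward sensitivity — the natural rule for a
  screening score.
* **Group tests.** Mann–Whitney U uses exact enumeration for pooled
  n ≤ 12 without ties and the tie- and continuity-corrected normal
  approximation otherwise; Fisher's exact uses the probability-mass
  two-sided definition (sum of tables no more likely than observed),
  with p = 1 for any zero margin. Both are verified against
  enumeration oracles in the tests.
* **ICC.** Interrater reliability is the one-way random-effects
  ICC(1) = (MSB − MSW)/(MSB + (k−1)·MSW) from the one-way ANOVA over
  subjects (matches pingouin's ICC(1,1)), with qualitative bands
  0.40–0.59 fair, 0.60–0.74 good, ≥ 0.75 excellent. A "one-way
  consistency" coefficient is sometimes requested in this field, but
  one-way models have no separate consistency form; ICC(1) is the
  defensible reading. Zero-variance ratings raise rather than return
  a conventional value.
* **Rounding.** Sensitivity/specificity are kept at full precision;
  the reporting layer rounds percentages half-up to integers and
  ratios to 2 decimals, matching customary clinical reporting. JSON
  reports always carry full precision.

## Pipeline

`run_study` is deterministic given its config (the config hash and
seed are recorded in the report provenance; no timestamps enter the
JSON, so identical configs produce byte-identical reports) and refuses
single-class cohorts. Input modes: cohort CSV (documented schema,
unknown columns preserved as covariates, malformed rows rejected with
their row number), a phantom directory (NIfTI pairs plus a
`stiffness.csv` supplying the reference standard, which a phantom
cannot carry), or the synthetic generator. Default fixed cutoffs
tabulated alongside each score's Youden cutoff: 0.34 for LSVR, 0.67
and 0.47 for LSVAR — the conventional operating points for these
scores (0.47 trades specificity for a minimal number of false
negatives). An optional second-reader simulation re-measures 20
patients with 5% volume CV and 5 HU attenuation error to populate the
ICC block. The CLI exposes `simulate`, `score`, `evaluate`, `report`
and `all`; exit codes are 0 (success), 2 (schema/config error) and
3 (degenerate study).

## Problem sizes

Default test and acceptance workloads: 200 simulated cohorts of
n = 141 for the stochastic AUC-ordering property, 100 random
instances (n ≤ 50) for the ROC/Youden oracle checks, 20 phantoms at
64³ × 2.5 mm for the measurement round trip, and 60 cohorts for the
median-convergence checks. The full suite runs in well under a minute.

## Known limitations

Phantoms are geometric, not anatomic; the LVCA flag for category 4 is
an input, not an image-analysis result; the cohort generator induces
dependence only through group membership; confidence intervals for
differences between correlated AUCs (DeLong's paired test) are out of
scope, as are multi-class ROC, partial AUC and any regression or
survival modeling.
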