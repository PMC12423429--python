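# Methods

## Problem and scope

`footmorph` quantifies two things about foot morphometry studies that
compare ultrasound (US) against MRI in people with and without plantar
fasciitis (PF):

1. **Muscle volume from serial cross-sections.** The flexor digitorum
   brevis (FDB) is imaged every 0.5 cm along its axis, yielding 15–25
   cross-sectional areas (CSAs, cm²) per foot. Two slice-sum estimators
   turn a CSA series into a volume.
2. **How trustworthy those measurements are.** Test–retest reliability
   (ICC, SEm, MDD) and between-modality agreement (Pearson r,
   Bland–Altman) for both the FDB volume and the plantar fascia thickness
   (mm, the clinical marker of PF).

The package consumes CSA values and thickness values, never images;
segmentation is upstream of its scope.

## Volume estimators

**Truncated cone.** Each consecutive slice pair bounds a conical frustum.
Areas are converted to equivalent-circle radii, r = √(A/π) — the only
radius definition consistent with feeding CSAs into a radius-based
formula — and the segment volume is the exact frustum expression

    V_seg = (1/3) π h (r² + rR + R²),

summed over the N−1 pairs. The sum is *exact* for any solid whose radius
profile is piecewise linear between the sampled positions (cylinders,
cones, frusta at any grid), which is the basis of the exactness tests.
No axial extrapolation happens beyond the first and last slice; an
optional `end_caps` flag appends a tapering cone of one slice-spacing
height at each end (default off, because the measurement protocol defines
the muscle extent by its visible slices).

**Cavalieri (cylinder).** Each slice contributes A·h; the volume is the
plain slice sum over all N slices, as used by semi-automatic volume
segmenters. Its axial extent therefore exceeds the truncated-cone extent
by exactly one spacing, and on a constant-area series the two estimators
differ by exactly one slice volume B·h — kept as a regression identity
rather than asserting any general ordering (none holds).

**Numerical notes.** The frustum formula is evaluated in a fixed operand
order so that it is bitwise symmetric in (r, R). Slice grids are strict by
default (gaps must equal the nominal spacing to 1e-9 cm); with
`strict_grid=False` the per-pair actual gaps are used. Zero-area interior
slices are legal and produce two abutting cones. ICC point estimates are
clamped at 1.0 to absorb float round-off in the ANOVA sums.

## Reliability chain

For an n-feet × k-trials complete-case matrix:

* **ICC(3,1)** — two-way mixed effects (subjects random, raters fixed),
  consistency, single measure: ICC = (MS_R − MS_E)/(MS_R + (k−1)MS_E)
  from the two-way ANOVA decomposition. The 95% CI is the Shrout–Fleiss
  F-inversion with df (n−1) and (n−1)(k−1). pingouin's ICC3 serves as an
  independent cross-check in the test suite, never as the implementation.
* **SEm** = SD·√(1−ICC). SD defaults to the sample SD of all n·k pooled
  individual measurements; `sd_mode="trial_means"` uses the SD of per-foot
  trial means instead (the definition is not standardized in the
  literature, so both are exposed; pooled is the default because SEm is
  meant to describe single measurements).
* **SEm 95% interval** = mean ± 1.96·SEm around the group mean.
* **MDD** (MDC₉₅) = SEm·1.96·√2, also reported as 100·MDD/mean (%).

1.96 is a fixed normal quantile throughout, never a t quantile — the
convention of the SEm/MDD literature.

## Agreement chain

Bland–Altman differences are first-listed minus second-listed method.
Bias = mean difference; LoA = bias ± 1.96·SD(diff) with sample SD
(ddof = 1); **LoA %** = LoA half-width ÷ the average of the two methods'
group means × 100 — a scale-free agreement number comparable across
measurands. The per-foot value entering a pair is the mean of its two
trials (`trial_handling="trial_1"` uses the first trial only; which of
the two a given study used is rarely stated, so both modes exist).
Correlations are reported as r and r² side by side, because published
tables sometimes label Pearson r columns "R²". Group contrasts use
Welch's t (robust default for unequal n and variance).

## Synthetic study generator

The generator emulates the study design stage by stage, with defaults
fixed at the study's population scale:

| parameter | default | unit | origin |
|---|---|---|---|
| feet, PF / non-PF | 18 / 38 | — | study design |
| fascia mean ± SD, non-PF | 3.94 ± 0.77 | mm | population parameters |
| fascia mean ± SD, PF | 5.21 ± 0.94 | mm | population parameters |
| FDB volume mean ± SD | 14 ± 4.5 | cm³ | population parameters |
| slice spacing | 0.5 | cm | imaging protocol |
| slices per foot | 15–25 | — | imaging protocol |
| σ_within (fascia / volume) | 0.077 / 0.45 | mm / cm³ | σ_between·√(0.01/0.99), giving true ICC ≈ 0.99 |
| US − MRI bias (fascia / volume) | −0.02 / −0.35 | mm / cm³ | agreement-table magnitudes |
| σ_method (fascia / volume) | 0.167 / 0.46 | mm / cm³ | √((LoA half-width/1.96)² − σ_within²) |

Noise is specified per measurand (two `NoiseSpec` instances, fascia in mm
and volume in cm³) because the units and magnitudes differ; a single
shared spec could not carry both. Seeds live in `StudyConfig`/function
arguments rather than inside the noise spec, so one run has one seed.

Per foot: the true fascia thickness and FDB volume are Gaussian draws
from the group parameters. Each foot's muscle is realized as a fusiform
(sinusoidal-radius) phantom whose length follows from its slice count and
whose r_max is solved from the drawn volume; trial noise enters as a
whole-series area scale factor, so a trial's slice-sum volume equals the
true volume plus additive Gaussian error while the CSA profile stays
shaped like a muscle belly. The US modality carries a persistent per-foot
offset drawn from N(bias, σ_method²), reproducing both the mean
inter-modality bias and the spread of the Bland–Altman differences.
Fascia trials consist of two images whose pair mean has SD σ_within.
Feet are allocated so that some PF participants are bilateral and a PF
participant's non-diagnosed foot joins the control pool — group
membership is per foot, mirroring pooled-feet designs.

What the generator does *not* emulate: image speckle or resolution,
probe-pressure artifacts, heteroscedastic or non-Gaussian error (the
error distribution of real re-measurements is unknown; Gaussian is an
assumption), anatomical irregularity beyond a smooth fusiform belly, and
within-participant correlation (exposed as `intra_participant_corr`,
default 0, matching the unadjusted pooling of feet). Passing tests
therefore demonstrate the statistical machinery recovers known truth
under this idealized model — not that real scans behave this way.

Degenerate draws: negative thickness values are truncated at 0 with a
logged warning; drawn volumes are floored at 0.5 cm³ (a vanishing muscle
is not physical); negative trial scale factors are floored at 0.

## Problem sizes used in validation

Monte-Carlo checks run at sizes chosen to make sampling error an order of
magnitude smaller than the tolerance being asserted: ICC recovery uses
500 feet × 2 trials × 200 replicates (mean estimate within ±0.01 of the
true 0.990, ≥90% CI coverage); Bland–Altman recovery uses 10,000 pairs
(bias and difference-SD within 5%, ~95% of differences inside the LoA);
the group-difference replication uses 100 studies of 36 PF / 76 control
feet, at which Welch power for p < 0.001 on the 1.27 mm fascia difference
is ≈ 0.999 (at exactly 18/38 feet the same test has power ≈ 0.89, so the
single-study default remains 18/38 while the replication check runs at
the doubled size).

## Known limitations

* Feet are treated as independent observations; no cluster correction for
  the two feet of one participant (a documented property of the design
  being emulated, not an oversight).
* The CSA→radius conversion assumes circular cross-sections; real FDB
  sections are elliptical, which biases nothing as long as the same
  convention is used throughout, but the "radius" is nominal.
* Complete-case only: a missing trial is an error, not an imputation
  target.
* The Shrout–Fleiss interval is asymptotic in the normal-theory sense;
  coverage at very small n (< 10 feet) can dip below nominal.
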