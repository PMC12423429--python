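# footmorph

Foot muscle volumetry from serial cross-sectional areas, plus the
test–retest reliability and method-agreement statistics used to decide
whether ultrasound can stand in for MRI in assessing plantar fasciitis.

Clinicians and researchers track two morphometric markers of plantar
fasciitis (PF): the thickness of the plantar fascia (mm) and the volume
of the flexor digitorum brevis (FDB) muscle (cm³). MRI is the reference
modality; ultrasound is cheaper, faster and portable. `footmorph`
implements the complete analysis chain such a validation study needs —
and a synthetic study generator with known ground truth, so the whole
chain can be exercised and verified end to end without patient scans.

## What it computes

**Volume from serial CSAs.** A muscle imaged every *h* = 0.5 cm yields
15–25 cross-sectional areas A₁…A_N. Two estimators:

* *Truncated cone*: radii rᵢ = √(Aᵢ/π); volume = Σ (1/3)πh(rᵢ² + rᵢrᵢ₊₁ + rᵢ₊₁²)
  over the N−1 consecutive slice pairs — exact whenever the radius is
  piecewise linear between slices.
* *Cavalieri (cylinder)*: volume = Σ Aᵢ·h over all N slices, the rule
  used by semi-automatic volume segmenters.

**Reliability** (per group × structure × modality × method, from the
two-trial repeated measures):

* ICC(3,1) — two-way mixed, consistency, single measure:
  (MS_R − MS_E)/(MS_R + (k−1)MS_E), with Shrout–Fleiss 95% CI;
* SEm = SD·√(1 − ICC); 95% interval mean ± 1.96·SEm;
* MDD (MDC₉₅) = SEm·1.96·√2, absolute and as % of the group mean.

**Agreement** (per method pair × group): Pearson r, Bland–Altman bias =
mean(first − second), limits of agreement bias ± 1.96·SD(diff), and the
LoA half-width as % of the pooled method means. Group contrasts (PF vs
non-PF) use Welch's t.

The statistical components are scikit-learn-style estimators
(`IntraclassCorrelation`, `ReliabilityAnalysis`, `BlandAltman`,
`VolumeEstimator`) with `fit`/fitted attributes and `get_params`, and
thin functional wrappers (`icc_3_1`, `sem`, `mdd`, `bland_altman`, …).

## Worked example

```python
import footmorph as fm

# volume of a single fusiform muscle phantom with known truth
shape = fm.ShapeSpec("fusiform_sine", length=10, r_max=1)
series = fm.sample_slices(shape, spacing=0.5)
tc = fm.truncated_cone_volume(series)
cav = fm.cavalieri_volume(series)
print(f"true volume      : {fm.true_volume(shape):.3f} cm^3")
print(f"truncated cone   : {tc.value:.3f} cm^3  ({tc.n_slices} slices)")
print(f"Cavalieri        : {cav.value:.3f} cm^3")

# a full simulated study (18 PF / 38 control feet, US + MRI, 2 trials)
bundle = fm.run_study(config=fm.StudyConfig(seed=42))
rel = bundle["reliability"]
row = rel[(rel.group == "non-PF") & (rel.structure == "fascia") & (rel.modality == "MRI")].iloc[0]
print(f"non-PF fascia (MRI): mean {row['mean']:.2f} mm, ICC(3,1) {row['icc']:.3f}")
print(f"SEm {row['sem']:.3f} mm, MDD {row['mdd']:.3f} mm ({row['mdd_pct']:.2f}%)")
```

prints

```
true volume      : 15.708 cm^3
truncated cone   : 15.643 cm^3  (21 slices)
Cavalieri        : 15.708 cm^3
non-PF fascia (MRI): mean 3.91 mm, ICC(3,1) 0.989
SEm 0.073 mm, MDD 0.203 mm (5.19%)
```

The truncated-cone estimate sits 0.4% below the analytic truth (the
linear-radius interpolation slightly undercuts a convex belly); the
simulated control-group fascia recovers its 3.94 mm population mean, an
ICC near the 0.99 the noise model implies, and an MDD of ≈0.2 mm — i.e.
a real change must exceed about 5% of the fascia's thickness to be
distinguishable from measurement error.

A CLI mirrors the library for shell use:

```sh
footmorph simulate --outdir data/            # synthetic slices.csv + thickness.csv
footmorph volumes --slices data/slices.csv --out volumes.csv
footmorph agreement --slices data/slices.csv --thickness data/thickness.csv --outdir tables/
footmorph report --seed 42 --outdir report/  # full end-to-end run
```

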