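# peridce

Three-dimensional intra- and peri-tumoural pharmacokinetics from breast
dynamic contrast-enhanced MRI (DCE-MRI).

`peridce` is a semi-automatic analysis tool for radiologists and imaging
scientists who want region-level kinetic parameters not only for a breast
tumour but also for the thin tissue layers immediately around it. Given a
dynamic T1-weighted series (one pre-contrast plus several post-contrast
volumes) and a rectangular ROI around the lesion, it

1. **segments the tumour in 3D** — the last post-contrast volume of the
   cropped series is collapsed to a 2D maximum intensity projection (MIP),
   a 2-cluster k-means separates enhancing from non-enhancing pixels, small
   2D objects are discarded, the resulting stencil is propagated through
   every slice and time point, a 4-cluster k-means on the masked first
   post-contrast volume refines the tumour edge, and only the largest 3D
   connected component is kept;
2. **builds four peri-tumoural shells** — stepwise morphological dilations
   of the tumour, hollowed so each shell is exactly one voxel thick,
   numbered 1–4 from the tumour boundary outwards;
3. **quantifies kinetics per region** — region-mean time–intensity curves
   are taken from the *unmodified* intensities, converted to absolute
   contrast-agent concentration with a reference-tissue model, and reduced
   to the standard semi-quantitative parameters.

## The model

With S₀ the pre-contrast region mean, S₁ the first post-contrast mean,
S_peak the post-contrast maximum and S_last the final mean:

```
E1    = 100% · (S1 − S0) / S0            initial percentage enhancement
Epeak = 100% · (Speak − S0) / S0         peak percentage enhancement
SER   = (S1 − S0) / (Slast − S0)         signal enhancement ratio
```

SER > 1 indicates washout, SER < 1 persistent enhancement. Absolute
concentration uses the reference-tissue approximation

```
C(t) ≈ (1/r1) · (S(t) − S(0)) / (T1_ref · S0_ref)     [mmol/L]
```

with breast adipose tissue as the reference (baseline T1_ref = 366 ms at
3 T, relaxivity r1 = 3.43 mM⁻¹s⁻¹); S0_ref is the adipose pre-contrast mean
measured from a healthy-breast crop, segmented by the same k-means machinery
(fibroglandular tissue is obtained analogously, with binary erosion to strip
the skin, which shares its intensity cluster). AUC is the trapezoidal
integral of C(t) in mmol/L × min.

A statistical layer covers the accompanying study design: pooled-variance
Student's t-tests on group summaries, Pearson correlation, Cronbach's α,
ICC(3,1) with F-based confidence intervals, and fixed-threshold
low-/high-grade classification metrics. A synthetic phantom generator
produces fat-suppressed-like 4D breast volumes (air, skin, adipose,
fibroglandular tissue, enhancing tumour, outward-decaying peri-tumoural
enhancement, additive noise) with exact ground-truth masks and curves, so
the whole pipeline is testable without patient data.

## Worked example

```python
import numpy as np
from peridce import PhantomSpec, RoiBox, generate_phantom, pipeline_run

spec = PhantomSpec(seed=42)                      # 40×80×80 voxels, 7 frames
series, truth = generate_phantom(spec)

tumour_box = RoiBox(y_range=(26, 54), x_range=(44, 74), z_range=(12, 29))
healthy_box = RoiBox(y_range=(24, 56), x_range=(2, 38), z_range=(4, 36))
result = pipeline_run(series, tumour_box, healthy_box)

p = result.params["tumour"]
print(f"tumour: E1={p.e1:.1f}%  Epeak={p.e_peak:.1f}%  SER={p.ser:.3f}  "
      f"AUC={p.auc:.2f} mmol/L x min")
for name in ["shell1", "shell2", "shell3", "shell4"]:
    c = result.concentrations[name].c[1]
    print(f"{name}: C(tp2)={c:.3f} mmol/L  SER={result.params[name].ser:.3f}")
```

prints

```
tumour: E1=150.4%  Epeak=150.4%  SER=1.099  AUC=9.23 mmol/L x min
shell1: C(tp2)=0.895 mmol/L  SER=1.093
shell2: C(tp2)=0.446 mmol/L  SER=1.096
shell3: C(tp2)=0.222 mmol/L  SER=1.109
shell4: C(tp2)=0.111 mmol/L  SER=1.108
```

The phantom's tumour was generated with E1 = 150 % and SER = 1.10 (washout):
the pipeline recovers both to within noise, and the first-post-contrast
shell concentrations halve with each voxel of distance from the tumour
border, mirroring the generator's peri-tumoural decay of 0.5 per shell. The
`result.table()` method returns the same numbers as a tidy DataFrame, and
`result.masks` holds the tumour, shell and reference-tissue masks as
NIfTI-writable volumes.

The same workflow is scriptable from the shell:

```sh
peridce phantom --config config.toml --seed 7 --out phantom/
peridce run-all --config config.toml --series phantom/phantom.nii.gz --out out/
```

Each subcommand writes its artifacts (NIfTI masks, CSV curves/kinetics)
plus a provenance JSON with the effective configuration, its hash and the
seed; re-running with the same seed reproduces the CSVs byte-for-byte.

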