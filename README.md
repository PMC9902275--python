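# isletpulse

Spatiotemporal analysis of pancreatic beta-cell responses imaged over a
microfluidic oxygen gradient: ratiometric Fura-2 calcium imaging, per-pixel
Fourier (spectral-centroid) frequency mapping, in-gel insulin immunosensor
calibration with limit of detection, and a rotational fluid-shear model of
hydrogel adhesion. It is written for experimentalists who acquire
two-channel time-lapse collages of cells cultured across an oxygen gradient
and want a reproducible route from raw TIFF stacks to "at which oxygen level
do calcium oscillations peak, and how much insulin was secreted".

## What it computes

**Calcium oscillation frequency versus oxygen.** From a two-channel stack,
the Fura ratio R = I₃₄₀/I₃₈₀ is formed per pixel; frames inside the
glucose-stimulation window are selected (dropping the stimulation-onset
overshoot frame); each pixel trace is leveled by the line through its
endpoints; and the DFT magnitude spectrum is reduced to a nominal frequency
— its center of gravity

&nbsp;&nbsp;&nbsp;&nbsp;f = 60 · Σₖ f_k |X_k| / Σₖ |X_k|,&nbsp;&nbsp;
f_k = k/(N·dt), k = 1…⌊N/2⌋ (DC excluded),

in oscillations/hour. Averaging the map down image columns and mapping
columns to %O₂ through the device gradient gives a frequency-vs-oxygen
profile whose maximum locates the oxygen level of fastest oscillation.

**Insulin detectivity and LOD.** Replicate (concentration, fluorescence
ratio) points are fit to a one-site saturation curve
R(C) = r0 + r_max·C/(kd + C); the limit of detection is the concentration
whose fitted response equals the blank mean plus twice the blank SD,
LOD = kd·2σ/(r_max − 2σ).

**Hydrogel shear adhesion.** Stir-plate rotation is converted to wall shear
stress through a Couette profile, τ = µ·ω·r/h; delamination series reduce to
(possibly censored) threshold records, and dimple microtextures are scored
by sidewall area gain, 100·count·perimeter·depth/base area.

A seeded synthetic-data generator produces two-channel stacks (oxygen-
dependent oscillation frequency peaking at 12% O₂, bleaching, overshoot,
noise, stitching banding) and noisy detectivity tables, so the entire chain
is testable without raw microscopy.

## Worked example

```python
from isletpulse import (PipelineConfig, StackConfig, run_spatial_pipeline,
                        DetectivityConfig, simulate_detectivity,
                        fit_calibration, limit_of_detection)

res = run_spatial_pipeline(
    PipelineConfig(stack=StackConfig(width=640, height=128), seed=1))
pk = res["peak"]
print(round(pk.o2_percent, 2), round(pk.freq_per_hr, 2), round(pk.period_min, 2))
# 10.3 13.53 4.43

pts = simulate_detectivity(DetectivityConfig(seed=1))
curve = fit_calibration(pts, model="saturation")
print(round(curve.kd, 1), round(limit_of_detection(curve).lod_pg_ml, 1))
# 481.0 22.8
```

The first line runs the full synthetic pipeline: a 640×128 px stack, 46
frames at 1-min intervals, stimulated 12–36 min, over a linear 0–20%
gradient. The recovered profile peaks at 10.3% O₂ with a nominal frequency
of 13.53 hr⁻¹ (4.43 min/cycle): the planted optimum is 12% O₂ at
13.5 hr⁻¹, and with a 24-frame window the spectral centroid recovers the
frequency to within a fraction of a DFT bin but localizes the peak only to
within ~2% O₂ (leakage bias of short untapered windows — see
`docs/methods.md`). The second block fits a noisy detectivity series whose
true parameters are kd = 475 pg/mL and closed-form LOD 25 pg/mL; this
realization fits kd = 481 and LOD = 22.8.

The same stages are available from the shell:

```
isletpulse simulate --out stack/ --width 640 --height 128 --seed 1
isletpulse profile --stack-dir stack/ --out profile.csv
isletpulse peak --profile-csv profile.csv
isletpulse lod --points-csv detectivity.csv
isletpulse shear --tests-csv shear_tests.csv
isletpulse run-all --out results/ --seed 1
```

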