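# Methods

## The experiment this package models

Pancreatic beta cells secrete insulin in response to glucose through a
cascade (glucose → ATP/ADP rise → K_ATP-channel closure → depolarization →
calcium influx → exocytosis) whose calcium arm oscillates on a scale of
minutes. When such cells are cultured over a microfluidic oxygen gradient
(0–20% O₂ across the field of view) and imaged ratiometrically with Fura-2,
the oscillation frequency varies with the local oxygen level, peaking at an
intermediate tension near 12% O₂ (about 13.5 oscillations/hour, one cycle
per ~4.4 min). The same devices carry an in-gel sandwich immunoassay whose
fluorescence ratio calibrates secreted insulin down to tens of pg/mL, and
the hydrogel's adhesion to the device is characterized by a rotational
fluid-shear test. This package implements the complete analysis chain for
all three measurements, plus a synthetic-data generator so the chain is
testable without any raw microscopy.

## Spatiotemporal frequency analysis

**Ratio stack.** Per pixel, R = I₃₄₀ / I₃₈₀. Pixels whose denominator falls
at or below `eps` (default 10⁻⁶ of the 380-channel dynamic range) in any
frame are masked, not clipped, so artifacts remain visible downstream. No
background subtraction is applied before the quotient (an optional constant
offset is available); raw ratios are reported, with no conversion to
absolute calcium concentration.

**Analysis window.** Frames with `stim_start ≤ t ≤ stim_end` (inclusive);
with `drop_first` the earliest selected frame — the stimulation-onset
overshoot — is removed. On the reference timeline (46 frames at 1-min
intervals, stimulation 12–36 min) this yields 24 frames spanning 13–36 min
(25 without the drop).

**Detrending.** Each windowed pixel trace is leveled by subtracting the
straight line through its first and last samples. The operation is linear,
idempotent, and exactly annihilates affine drifts (photobleaching to first
order); it also removes any time-constant offset, which is why static
stitching banding does not contaminate the frequency map.

**Spectral centroid.** With DFT magnitudes |X_k| at f_k = k/(N·dt),
k = 1…⌊N/2⌋ (DC excluded, Nyquist included once for even N), the per-pixel
nominal frequency is

    f_cog = 60 · Σ f_k |X_k| / Σ |X_k|   [oscillations/hour]

Magnitude weighting (not power) is used. A series with an identically zero
spectrum reports 0. DC exclusion plus endpoint detrending is required for
the centroid to be meaningful: without them, baseline offsets drag every
value toward zero. No taper is applied before the transform.

**Profile and peak.** The map is averaged over rows ("flattened
vertically") to give frequency versus column; the device gradient maps
columns to %O₂. The peak is the profile argmax (optionally after a moving
average, default off = width 1); ties resolve to the lowest column index
and are flagged non-unique. Display normalization of the map (min–max to
[0, 1]) is for visualization only; profiles and peaks use unnormalized
frequencies.

**Known limitation — leakage bias of the short-window centroid.** With
N = 24 samples the DFT bins are 2.5 hr⁻¹ apart and an untapered off-bin
tone leaks across the whole grid. The centroid of a pure sinusoid is then
a non-monotone function of its true frequency (phase-averaged centroid at a
true 13 hr⁻¹ exceeds that at 13.5 hr⁻¹), so on synthetic single-tone input
the profile peak localizes only to within roughly ±2% O₂ of the true
optimum and the recovered peak frequency carries a bias of up to about one
bin. The recovered period (60/f) correspondingly resolves only to roughly
±0.05–0.2 min and whether it rounds to 4.4 versus 4.5 min depends on the
noise realization. Real calcium oscillations are broadband, which softens
but does not remove this effect; a taper or zero-padding would reduce it
but is deliberately not applied because the analysis chain mirrors the
plain FFT-centroid procedure. Tests assert the frequency to one DFT bin
and the peak position to 20% of the 12% O₂ optimum, which is what the
estimator actually resolves at this window length.

**Memory.** The frequency map is computed in row blocks (`block_height`),
so collage-scale stacks (13,156 × 2,556 px) can be processed with bounded
peak memory; block processing is bit-identical to whole-image processing.

## Synthetic-data generator

The generator emulates the acquisition geometry, not cell biophysics:

- **Gradient**: linear in column position between 0 and `o2_max`
  (logistic option available), monotone ("half") or mirror-symmetric
  ("full"). The linear form is the simplest monotone map consistent with
  the device's stated 0–20% endpoints.
- **Frequency field**: Gaussian bump
  f(O₂) = f_base + (f_peak − f_base)·exp(−(O₂ − o2_peak)²/(2·w²)) with
  defaults f_base = 6, f_peak = 13.5 hr⁻¹, o2_peak = 12%, w = 4% O₂. Only
  the peak location/height are anchored to reported physiology; the shape
  is a generator design choice.
- **Pixel trace**: baseline 1.0 ratio units + bleach (−0.002/min) + during
  the stimulation window an oscillation amplitude 0.15·sin(2π f (t −
  stim_start)) — phase locked to the glucose bolus — plus a single
  overshoot frame (amplitude × 3) at stimulation onset, so the
  window-selection step has something to drop.
- **Channels**: the 380 nm channel is a 1000-count plateau plus 0.5%
  detector noise; the 340 nm channel is (target ratio + N(0, 0.02) ratio
  noise + banding) × the 380 channel, so the quotient is exact in the
  noise-free case.
- **Banding**: ±0.03 ratio-unit square wave per 80-px column tile,
  emulating collage-stitching offsets. Being constant in time it is
  removed exactly by endpoint detrending.
- **Seeding**: one integer seed; independent sub-streams per channel via
  `numpy` `SeedSequence.spawn`. Identical seeds give identical stacks
  bit-for-bit.

What the generator does **not** model: the mechanistic dual-oscillator
feedback (glycolytic + electrical) that produces real islet oscillations,
gas diffusion–reaction in the channels, optics/PSF, cell morphology, or
spatially incoherent phase. Passing tests therefore demonstrate that the
analysis chain recovers planted spatio-spectral structure at realistic
noise, not that it would resolve any particular biology.

## Insulin sensor calibration

Replicate fluorescence ratios (signal/background) versus concentration are
fit by least squares to a one-site saturation (Langmuir) curve
R(C) = r0 + r_max·C/(kd + C) (antibody-capture assays saturate; a linear
model is available for narrow ranges). Blank statistics come from
replicates at C = 0 (falling back to the lowest concentration's spread,
with a warning). The limit of detection is the concentration whose fitted
response equals the blank mean plus twice the blank SD — closed form
kd·2σ/(r_max − 2σ) for the saturation model, 2σ/slope for the linear one —
and concentration inversion uses the exact inverse
C = kd·(R − r0)/(r0 + r_max − R). With the default synthetic configuration
(r0 = 1, r_max = 2, kd = 475 pg/mL, σ = 0.05) the closed-form LOD is
exactly 25 pg/mL; fitting noisy replicates (5 per level, 6 levels)
recovers a median LOD within 20% of that value across 100 seeds. The
median sits a little *below* 25 because the sample SD of 5 blank
replicates is a downward-biased estimator of σ.

## Shear adhesion model

The stir-plate test is modeled as plane Couette flow: at rotation rate
`rpm`, ω = 2π·rpm/60, edge velocity u = ω·r, and with a no-slip condition
at the gel the wall stress is τ = µ·u/h. Defaults r = 7.5 mm (half the
1.5 cm gel width), µ = 10⁻³ Pa·s (water), and h = 75.5 mm; the gap value
is *calibrated* so that 125 rpm ↦ 1.30 mPa, the unmodified-gel baseline,
and the worked example is therefore a regression check on the
parameterization, not an independent physical prediction. Whether r should
be the gel half-width, half-diagonal, or stir-bar radius is not
determined; all three geometry parameters are explicit inputs.

Delamination thresholds take sorted (rpm, delaminated) observations; the
threshold is the lowest delaminating rpm, right-censored at the maximum
tested rpm when nothing delaminates (e.g. star-textured gels surviving
1200 rpm) and left-censored when the first tested rpm already delaminates.
Records where a gel delaminates at low rpm but survives a higher one are
rejected as contradictory. No survival modeling is applied to censored
records.

Texture area gain treats each dimple as adding a sidewall band:
gain% = 100·count·perimeter·depth/base area, with the cross-section
perimeter computed from the circumscribed radius (regular 3/4-gon; 5-point
star with inner/outer radius ratio 0.5 by default). At equal circumscribed
radius the perimeters order triangle < square < star, reproducing the
qualitative adhesion ranking. Published per-shape gain percentages are not
reproduced numerically because the dimple in-plane dimensions are not
specified; the calculator takes geometry as input.

## Statistics

Group comparisons use the unpaired two-tailed Student t test (classical
pooled variance; Welch available via `equal_var=False`) with star levels
* p < 0.05, ** p < 0.01, *** p < 0.001 applied strictly. (Reported
experimental figures sometimes star a p = 0.057 jump; this package's star
mapping follows the stated thresholds and would not.)

## Problem sizes and determinism

Tests and the acceptance script run a reduced collage (640 × 128 px,
46 frames, 24-frame window) — large enough that column averaging and the
gradient mapping behave as at full scale, while keeping the whole suite in
seconds. Full-scale collages run through the same code via `block_height`.
All randomness derives from explicit integer seeds; the pipeline derives
stage seeds deterministically from one top-level seed, and identical
configurations reproduce identical outputs bit-for-bit.
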