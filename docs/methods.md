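# Methods

## The measurement

Imaging photoplethysmography (iPPG) maps tissue perfusion from ordinary
video. Under green illumination (~535 nm), arterial blood absorbs
strongly, so the light a camera collects from tissue dips slightly with
every systole. The dip is small — a fraction of a percent to a few
percent of the mean reflected intensity — and spatially heterogeneous:
well-perfused tissue pulses, devascularized tissue does not. The
quantity this package maps is the **amplitude of the pulsatile
component (APC)**: the peak-to-peak excursion of the ensemble-averaged,
one-cardiac-cycle PPG pulse, expressed in percent of the local DC
intensity. APC is used as a perfusion index.

The processing chain, given a grayscale video and a time-synchronized
single-lead ECG:

1. **Motion compensation.** Each frame is tiled into 8×8-px segments;
   per-segment lateral offsets relative to a reference are estimated by
   gradient optical flow, and the motion-related intensity component is
   subtracted per pixel.
2. **PPG extraction.** The frame is tiled into 2×2-px ROIs sharing
   borders without overlap. Each ROI's waveform is the frame-by-frame
   mean pixel value. A floating-window DC baseline — mean over a window
   whose length equals the duration of the cardiac cycle containing the
   sample — divides the waveform (AC/DC); unity is subtracted and the
   sign inverted so the output rises with blood volume. A zero-phase
   low-pass at 4 Hz (4th-order Butterworth, forward–backward) removes
   noise above the cardiac band without displacing pulse extrema.
3. **Pulse analysis.** The waveform is cut at the ECG R-peaks; the
   pulses of 12 subsequent valid cycles are truncated to the shortest
   and averaged sample-wise; APC = (max − min) × 100 of the mean pulse.
   The span of the 12 cycles (6 s at 120 bpm to 16 s at 45 bpm) is the
   temporal resolution of the map.
4. **Mapping.** Per-ROI APC values form the perfusion map; regional
   statistics use 60×60-px windows (mean ± sample SD, ddof = 1), and
   gradients may be reported as percent of the maximum regional mean.

## Motion compensation in detail

Camera intensity varies for two reasons — motion and blood volume — and
the estimator must not confuse them. Three design choices follow from
this:

**Illumination-invariant flow.** Blood volume modulates reflectance
multiplicatively and is nearly uniform within an 8×8-px segment. The
default estimator therefore works on log-intensity and augments the
brightness-constancy system with a per-segment uniform-brightness
nuisance term (implemented by segment-mean-centering the gradients and
temporal differences). The blood term is absorbed by the nuisance
exactly; only spatial structure drives the offsets. Without this, a
bare two-parameter least squares projects the pulsation onto the
gradient span and the subtraction removes most of the signal. The bare
system remains available (`illumination_invariant=False`); it is exact
for rigid shifts of static scenes and is what the closed-form
translation tests exercise.

**Band-limited offsets.** Tissue bulk motion (respiration ~0.2–0.4 Hz,
peristalsis, handling) is slow. Offset traces are smoothed by a
zero-phase low-pass (default 1.5 Hz; the pipeline further caps the band
at 0.7× the detected cardiac fundamental). This passes genuine motion
with margin, rejects the broadband estimator noise that would otherwise
be injected into every pixel of a segment (and biases APC upward at low
modulation depths), and guarantees by construction that the compensator
cannot subtract cardiac-band signal. The cost is that genuine
cardiac-frequency tissue motion (ballistocardiographic coupling) is not
compensated; the acquisition geometry this models minimizes it, and
compensating it is in any case ill-posed — at the cardiac frequency,
motion and blood volume are indistinguishable to an intensity sensor.

**Registration-style subtraction.** The subtracted motion component is
`raw(p) − raw(p + d)`: the difference between the frame and itself
resampled (cubic spline) back to the alignment target, using the
segment's offset. Its first-order expansion is the classical
gradient×offset term, which is also available (`method="linear"`) and
adequate below ~2 px; the resampled form stays accurate at the
several-pixel excursions breathing produces, and leaves the blood-volume
modulation — which moves with the tissue — untouched. The alignment
target is the mean tissue position over the record, so map coordinates
are not biased toward wherever the reference happened to sit.
Displacements beyond the ~2 px linearization range are estimated by
accumulating inter-frame flow (`mode="auto"` switches automatically);
conservation (`corrected + motion_component == raw`, bit-exact) holds
regardless.

Segments whose centered 2×2 normal matrix is ill-conditioned
(condition number > 1e3, e.g. texture-free regions) are flagged and all
ROIs inside them are masked in the map rather than silently zero-filled.

## Floating DC window and edge handling

The DC window is centered on each sample (centered windows are unbiased
for linear drifts) with length equal to the enclosing cardiac cycle's
duration; a whole period of any cardiac-frequency component integrates
to (near) zero, so the baseline tracks illumination drift without
absorbing the pulse. Samples whose full window would overrun the record
are computed with a clipped window for filtering continuity but excluded
from pulse analysis — no data is fabricated at the edges. A cycle enters
the ensemble only if the duration gate (0.30–2.0 s, i.e. 30–200 bpm)
passes for it and its neighbors and all of its frames are fully usable;
below 8 usable cycles the analysis refuses (with 8–11 it proceeds and
flags `below_target_cycles` in the map metadata).

## R-peak detection

Pan–Tompkins-style: 5–30 Hz band-pass (zero-phase), squared derivative,
150 ms moving-window energy, candidate peaks at ≥300 ms spacing, an
adaptive threshold at 20% of the median strong-beat energy, and
refinement of each candidate to the local maximum of the raw signal
within ±50 ms. On synthetic ECG with 10% heart-rate variability and
20 dB SNR this localizes every R-peak within ~3 ms with no spurious or
missed detections; anything within ±10 ms is adequate here, since pulse
cutting is quantized to the 25.6 ms frame interval anyway.

## The synthetic generator

The generator is the oracle for every pipeline stage. Frames follow

    frame(p, t) = quantize( [T · (1 − depth · pulse)](p − offset(t)) · gain(p) + noise )

where `T` is a smooth positive reflectance texture (Gaussian random
field, default correlation length 8 px, mean 180, SD 25 intensity
levels), `depth` the configured peak-to-peak modulation map (0–5%),
`gain` a static illumination field, `offset(t)` a sinusoidal breathing
translation (default 0.25 Hz), and `noise` white sensor noise before
optional 8-bit quantization. The matching ECG places QRS-like wavelets
at the drawn R-times (mean interval 60/HR, coefficient of variation
`hrv_frac`, intervals clipped to the physiological gate).

Two generator choices matter for oracle consistency:

- **Band-limited default pulse template.** The template is a
  two-harmonic, unit-peak-to-peak pulse. A sharper upstroke+decay shape
  is available, but its energy above the 4 Hz analysis band means any
  faithful 4 Hz zero-phase pipeline recovers less than its nominal
  peak-to-peak, making the closed-form expected APC (depth × 100)
  unattainable by construction rather than by implementation error.
  Physiological PPG pulses at intraoperative heart rates are smooth, so
  restricting the template to the analysis band is not a loss of realism
  for the quantity being validated.
- **Absolute-time pulse layout.** The template is evaluated against time
  since the last R-peak on a nominal-period clock (clamped at cycle
  end), not rescaled per cycle: pulse extrema positions do not depend on
  cycle duration, which is exactly the property that makes R-gated
  ensemble averaging robust to heart-rate variability.

What the generator does **not** emulate: wavelength-dependent tissue
optics, specular highlights beyond the static gain term, non-rigid
deformation (the affine "peristalsis" mode is a global stretch),
venous/respiratory intensity modulation, and ectopic beats. Passing
tests therefore demonstrate correct recovery of the modeled signal
family, not clinical performance.

## Problem sizes and defaults

Desk-scale validation uses 128×128-px scenes at 39 fps for 15 s
(~585 frames, 4096 ROIs) — large enough for four depth zones of 1024
ROIs each while a full pipeline run takes a few seconds; the full-frame
752×480 geometry is exercised through the grid arithmetic (60×94
segments, 240×376 ROIs). Depth zones {0.5, 1, 2, 3}% span the clinically
reported perfusion-index range (~0.3–2.6%). Sensor noise σ = 1 intensity
level on a mean level of 180 makes the 0.5% zone's swing (0.9 levels)
sub-LSB at 8 bits — recovery there relies on noise dither, the hardest
realistic condition; the generator warns when a scene enters this
regime.

Key defaults: segment 8 px; ROI 2 px; cutoff 4 Hz, order 4; ensemble 12
cycles, floor 8; cycle gate 0.30–2.0 s; condition limit 1e3; max shift
16 px; linearization range 2 px; offset band 1.5 Hz (≤0.7× cardiac);
aggregation window 60 px; sample SD throughout.

## Numerical conventions and degenerate inputs

Half-open cycle intervals [R_i, R_{i+1}) — every instant belongs to
exactly one cycle. Pulse-length reconciliation by truncation to the
shortest pulse, never resampling. Percent-of-max ties broken by first
index; exactly one region reports 100. Non-positive DC masks the ROI
(division safety). Frame stacks with interval jitter above 0.25/fps are
rejected rather than resampled — ensemble averaging assumes a regular
frame grid. Flatline ECG, too-few beats, insufficient video/ECG overlap
(<6 s), and sub-segment images all raise typed errors naming the stage.
The analysis path contains no random numbers: re-running a configuration
on the same inputs is bit-identical.

## Known limitations

- Cardiac-frequency tissue motion is deliberately outside the
  compensator band (see above).
- Segments near the image border see content enter and leave the field
  of view; their offsets are less reliable (mirror-boundary resampling),
  which shows as mildly elevated map error in the outermost ROI rows
  and columns under large motion.
- The synchronization index (mean-pulse amplitude over mean individual
  amplitude) is one reasonable formalization of pulse-train coherence,
  chosen for being dimensionless, bounded in [0, 1], and exactly 1 for
  identical aligned pulses; other definitions exist.
- A sub-ROI (< 2 px) registration ambiguity at sharp perfusion
  boundaries is inherent: the map is reported in aligned camera
  coordinates, and a boundary ROI legitimately mixes both sides.
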