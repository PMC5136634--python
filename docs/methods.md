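# Methods

## The synthetic phonation model

`synth.generate_gaw` produces a quasi-periodic pulse train standing in for
the glottal area waveform of a sustained vowel. Each cycle is a
piecewise-smooth pulse on a constant area floor:

* **Pulse shape.** A raised-cosine opening limb and a raised-cosine closing
  limb joined at the peak. The open phase spans `open_quotient · T`; the
  two limb durations are in the ratio `speed_quotient`, which makes the
  programmed open quotient, speed quotient, and their derived quotients
  (ASQ, SI, CQ, RQ) exact ground truths.
* **Area floor.** `gap_fraction · peak_area_px` models the posterior
  glottal chink common in female phonation: the glottis never fully closes,
  and min/max area (the glottal gap index, GGI) equals `gap_fraction` by
  construction.
* **Perturbations.** Cycle periods carry i.i.d. zero-mean Gaussian noise on
  the log scale, amplitudes on the dB scale. For an i.i.d. N(0, σ²)
  sequence the mean absolute first difference is 2σ/√π, so σ is chosen to
  make the realized mean |ΔT| and mean |Δ20·log₁₀(peak)| match the
  requested `jitter_ms` and `shimmer_db` directly — the same
  consecutive-cycle definitions the analysis estimates (mJT, mSH).
* **Left/right halves.** Each half is half the pulse, time-shifted by
  ±`phase_asym · T/2`, so the normalized left−right peak-time offset (PA)
  equals `phase_asym` exactly. Frame noise is added in equal halves after
  the split, so `left + right == total` holds identically.

Defaults emulate a vocally healthy adult female: F0 = 176 Hz (the corpus
generator draws per-recording F0 from 176 ± 11 Hz), 15 kfps master rate,
110 generated cycles (≥ 106 analyzable after trimming partial edge cycles),
open quotient 0.9, speed quotient 1.25, gap fraction 0.05–0.07, phase
asymmetry −0.02, jitter 0.30 ms, shimmer 0.20 dB, additive area noise 2 px
on a 4000 px peak. The corpus size (20 recordings) and the rate grid
(1–15 kfps in 1 kfps steps, nearest-preceding-frame decimation) are the
study conditions of the sensitivity experiment; 106 cycles is the analysis
window length, following the convention that perturbation measures need at
least ~100 cycles to stabilize.

### What the generator does not emulate

Mucosal waves, irregular/aperiodic phonation, segmentation artifacts from
real endoscopic imagery (glare, motion, varying illumination), and
endoscope-distance effects on pixel scale. Tests passing on this corpus
demonstrate that the *estimators and statistics* behave as specified, not
that real clinical recordings would yield the same absolute values.

## Frame rendering and segmentation

`render_frames` draws each frame as a dark vertical lens (two independent
half-ellipses sharing the vertical midline) on a bright background. Half
widths are found by bisection so the dark pixel count matches the requested
area; the right half is fitted against the residual of the left so the
total tracks `total_area` within rasterization granularity (a quarter-pixel
vertical offset of the lens center removes the row-pair degeneracy that
would otherwise double the granularity). Segmentation is deliberately
plain: global threshold, largest 4-connected component inside an optional
ROI, minimum-size filter. The left/right split uses the major principal
axis of the time-union mask — per-frame axes are undefined when the glottis
closes — with on-axis pixels assigned to the left side so the partition is
exact. Robustness on real clinical video is out of scope.

## Cycle detection and phase landmarks

Cycles run from opening instant to opening instant. Detection is
two-stage for robustness down to ~4 samples per cycle:

1. candidate cycles are bracketed by upward crossings of the mid-level
   (baseline + half the global range);
2. each boundary is refined to the **takeoff frame** — the last sample at
   or below the closure level before the rise — or, when no sample reaches
   the closure level inside the bracket (low frame rates), the last minimal
   sample.

The closure level is `c = baseline + closure_threshold_rel · (cycle max −
baseline)` with `baseline` the global minimum area. Landing the boundary on
the takeoff frame (rather than the first frame above `c`) matters: both
limbs then carry their threshold-crossing frame symmetrically, which
removes a ~1-frame bias in the opening/closing durations and keeps speed
quotient recovery within ±0.025 at 15 kfps.

**Closure convention.** With the default `closure_threshold_rel = 0`,
closure would require dropping strictly below the global baseline, so no
frame is ever closed: the open quotient is identically 1. This is the
posterior-gap regime — an area floor above zero means the glottis never
closes — and it makes OQ rate independent by construction. Setting the
threshold to 0.01 or 0.05 reproduces the literature's 1%/5%-of-maximum
closure conventions; a small positive value (10⁻³) placed just above the
floor recovers the programmed closed phase and is what the recovery suite
uses. Per-cycle phase durations use the cycle-local maximum in `c`; the
takeoff frame itself counts as open, so `opening + closing == open`
exactly.

The analysis window is the first 106 complete cycles. Frame k corresponds
to time k/fs, cycles are half-open `[t_start, t_end)`, and `T` is computed
with the same floating-point expression everywhere — rank-based statistics
downstream must never see last-ulp differences between cells that are
equal by construction.

## Parameter estimators

All per-cycle quantities are computed cycle by cycle and averaged; cycles
where a quantity is undefined (zero closing duration for SQ/RQ, flat cycle
for AMQ, zero dynamic range for shimmer pairs) are excluded with a warning,
and a parameter with no valid cycle at all becomes an explicit NaN sentinel
with a reason code — never a silent zero.

* MADR is the most negative raw first difference of the total area within
  a cycle (px/frame); no derivative smoothing. AMQ = dynamic range / MADR.
* Amplitude dB scaling is 20·log₁₀ on areas. The shimmer percentage SH
  normalizes mSH by the mean dB-scaled dynamic range **re 1 pixel**; this
  makes SH depend on the pixel scale of the recording. It is the literal
  reading of the defining ratio, and it is flagged here loudly.
* AVI is the dB-scaled coefficient of variation 20·log₁₀(SD/mean) of the
  per-cycle dynamic ranges (sample SD, ddof = 1).
* Spectral measures operate on the mean-removed, Hann-windowed analysis
  window, zero-padded to ≥ 4× its length. Harmonic band k collects bins
  within ±0.12·F0 of k·F0 (k = 1 … Nyquist/F0), a bandwidth wide enough for
  jitter-broadened harmonics at 106-cycle windows; F0 comes from the
  detected cycles. HI and HNR use the plain band split, and
  `E_harm + E_noise == E_total` holds to machine precision. NNE uses the
  *estimated* noise energy: the mean noise density of the between-harmonic
  bins extrapolated across the whole spectrum, since the noise floor
  continues underneath the harmonic peaks. A plain complement would be
  biased by the ~24% band coverage (≈ −1.2 dB for pure noise); the
  extrapolated estimator reports ≈ 0 dB on white noise and large negative
  values on nearly periodic signals, as an NNE should. HNR is capped at
  ±120 dB when one energy vanishes; SPF is 10·log₁₀(GM/AM) of the power
  coefficients (DC excluded) and is ≤ 0 by the AM–GM inequality.

## Rate decimation

A slower camera observes a subset of instants; it does not low-pass the
scene. Output frame j at rate r therefore holds master frame
⌊j·master/r⌋ (exact integer arithmetic via rational ratios). Non-divisor
rates (e.g. 15 → 14 kfps) produce alternating 1- and 2-master-frame steps.
This has a real consequence for difference-based parameters: the per-frame
maximum declination rate at a non-divisor rate can be inflated by up to 2×
relative to uniform sampling at the same rate. The per-second invariance
MADR·fps ≈ const therefore holds — and is tested — across
*integer-divisor* rates once sampling resolves the closing limb (rates
≥ 20·F0); across all rates only the monotone trend |MADR| decreasing with
fps is asserted.

## Stability statistics

Normality screening uses Shapiro–Wilk plus the Lilliefors variant of
Kolmogorov–Smirnov (constant samples count as non-normal by convention);
the pipeline is nonparametric throughout. The Friedman test treats
recordings as blocks and rates as treatments; a parameter that passes the
omnibus gate (p ≥ 0.05) skips pairwise testing and is Group 1 directly.
Pairwise Wilcoxon signed-rank tests run for all 105 rate pairs with the
zero-difference discard convention, exact p-values for n ≤ 25 pairs and the
normal approximation above; an all-zero-difference pair is non-significant
by convention. The corrected level is α/14 — each rate participates in 14
comparisons — kept at that value (not α/105) deliberately.

Interval merging is greedy left-to-right: a run of consecutive rates grows
while the next rate has no significant pair with any member of the run.
An interval is additionally marked *gray* when it does not differ from
either neighboring interval while the neighbors differ from each other;
gray marks are reported but group assignment uses the plain partition.
Group rules: one full-span interval → 1; final interval reaching the top
rate with span ≥ 2 → 2; else any strictly interior interval with span ≥ 4
→ 3; else 4.

Under an i.i.d. null across rates the pipeline is calibrated: Friedman
p-values are uniform, and fewer than 10% of parameters leave Group 1 at the
corrected level (both are tested over seeded replicates).

## Problem sizes and determinism

The synthetic experiment uses 20 recordings × 15 rates × 106 cycles —
the full design, no scaled-down surrogate — and completes in seconds.
Every stochastic component (corpus generation, recovery suite, null
calibrations) derives from a single integer seed; identical parameters give
bit-identical waveforms.

## Known limitations

* SH and AVI depend on the pixel scale through the 1-px dB reference;
  comparisons across spatial resolutions need a common reference.
* The closure threshold changes OQ qualitatively (1.0 at threshold 0 versus
  the programmed value at small positive thresholds); any reported OQ must
  state its threshold.
* Cycle landmarks have one-frame granularity; perturbation measures at low
  rates are dominated by the quantization floor (mJT ≤ one frame duration
  on jitter-free input), which is precisely the sensitivity the pipeline is
  built to expose.
* The Wilcoxon exact/approximate switch at n = 25 and the tie handling
  follow common conventions; other software may differ in borderline
  p-values near the corrected threshold.
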