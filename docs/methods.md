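# Methods

## Signal model

A dynamic chest radiograph sequence is modelled as, for lung-field pixels,

    I(x, y, t) = B - A(x, y) * s_card(t) + R * s_resp(t) + e(x, y, t)

and for ventricle-ROI pixels

    I(x, y, t) = B + V * s_card(t) + e(x, y, t)

with baseline `B`, per-pixel perfusion amplitude `A(x, y)` (pixel-value
units), a unit-amplitude zero-mean cardiac waveform `s_card`, a
low-frequency respiratory residual `R * s_resp` (breath-hold is imperfect),
ventricle amplitude `V`, and i.i.d. Gaussian noise `e` with standard
deviation `sigma`. The key physiological facts encoded are (i) lung and
ventricle oscillate in anti-phase — during systole the ventricle empties
toward the lungs — and (ii) the oscillation amplitude over a lung region is
proportional to regional perfusion. Values are clipped to
`[0, saturation_level]`, matching a detector whose 16-bit range saturates
near 58,000.

## Perfusion mapping

**Filtering.** Respiratory and cardiac components are separated in the
frequency domain: a 4th-order Butterworth high-pass with cutoff 0.85 Hz,
applied forward–backward (`sosfiltfilt`). Zero phase matters because the
downstream statistic is a phase-sensitive correlation; the cost is that the
effective magnitude response is the squared single-pass response, so a
1.25 Hz cardiac tone at 15 frames/s is passed at gain 0.96 (amplitude),
not 1. Tests oracle against the designed filter's transfer function rather
than idealized pass/stop values. The minimum series length is 9 frames; the
reflect-padding length is capped at `n - 1` for short series.

**Reference signal.** `PC_lv(t)` is the high-pass-filtered mean over the
ventricle ROI (a 25 × 25 mm square placed medially). The heart rate is the
dominant peak of its zero-padded periodogram inside 0.85–3.0 Hz (51–180
beats/min); a peak below five times the in-band median power, or a
numerically flat ROI, raises "no cardiac component detected". The cardiac
period in frames (`frame_rate / f_peak`, rounded) sets the window length.

**Windowed correlation.** For every lung-field pixel, `CCv(x, y, t)` is the
Pearson correlation between `-PC_lv` and the filtered pixel series over a
centred window of one cardiac period, rounded up to an odd number of frames
with a floor of 5. One period is the shortest window over which phase
agreement between two oscillations is meaningful; odd length keeps the
window symmetric about its centre frame. Edge frames where the full window
does not fit are excluded (no partial windows, which would bias the
correlation). The implementation uses cumulative-sum sliding window moments
and is tested to agree with a naive per-pixel `corrcoef` double loop to
1e-10; it is exactly invariant to per-pixel affine rescaling.

Numerical policies: a window whose pixel variance falls below
`(1e-9 x saturation_level)^2` per frame is treated as signal-free — its CCv
is 0 and flagged undefined, so dead detector regions do not abort a run.
Pixels at the saturation level in more than 10% of frames are undefined
throughout. `MaxCCv` is the maximum of defined CCv values per pixel; pixels
with no defined window are NaN and excluded from all sums.

**What MaxCCv measures.** The expected correlation of a noisy oscillation
with a clean reference is `sqrt(s / (s + n))` where `s` is the (filtered)
signal power `(A g_sig)^2 / 2` and `n` the filtered noise power
`sigma^2 g_noise`; the tests verify this closed form over hundreds of
replicate pixels. Consequently MaxCCv is a *monotone but saturating*
function of amplitude: at high signal-to-noise ratio both lungs sit near
1.0 and the left/right ratio compresses toward 0.5. The blood-flow ratio is
therefore a relative perfusion surrogate — ordering and laterality are
preserved (the amplitude-ladder suite checks strict monotonicity), but the
numeric ratio is not an amplitude fraction.

## Blood-flow ratio

Per-lung sums of defined MaxCCv values, then
`BFR_affected = Sum_affected / (Sum_left + Sum_right)`; the two sides share
one denominator, so `BFR_affected + BFR_intact = 1` identically. Negative
MaxCCv values (possible in pure-noise pixels) are summed as-is by default —
the definition says "sum", not "sum of positive parts" — with a
`clip_negative` option exposing the alternative. Pixels are unweighted; a
nonpositive total raises "no perfusion signal".

## Postoperative prediction

The 19-segment model assigns 3/2/5 segments to the right upper/middle/lower
lobes and 3/2/4 to the left upper division/lingula/lower lobe (right 10,
left 9). Segment counting scales the preoperative value by the fraction of
segments remaining; perfusion weighting keeps the intact lung's BFR share
whole and scales only the affected side's share by its remaining-segment
fraction. When `BFR_affected` equals the affected side's segment share of
19, the two predictors coincide exactly — an identity the tests check for
every lobectomy type. Segmentectomies are supported by passing an explicit
resected-segment count. Multi-lobe resections sum segment-wise.

Percent-of-predicted values divide by a predicted-normal reference supplied
as an input column: no spirometric reference equation is bundled, because
which age/height/sex equation applies is population-specific; the cohort
schema records the values, not the formula. Risk-band thresholds belong to
the upper band (exactly 70% → "≥70"), a convention the band tests pin down.

## Agreement statistics

Standard formulations behind a small surface: OLS/correlation via
`scipy.stats.linregress`, the pooled-variance t test via `ttest_ind`
(degenerate zero-variance equal-mean groups reported as t = 0, p = 1), and
Bland–Altman computed directly: differences `a - b`, sample SD (n − 1),
limits of agreement at mean ± 2 SD exactly (not 1.96 SD), percent of points
within the limits, and a proportional-error OLS of differences on pairwise
means. Blood-flow ratios enter agreement statistics multiplied by 100 so
differences read in percentage points. Complication-rate tables report
per-band and overall percentages; empty bands are absent, not zero.

## Synthetic data: what it does and does not emulate

The imaging simulator reproduces the acquisition geometry (1024 × 1024
matrix at 0.417 mm pitch, 15 frames/s, ~10 s breath-hold, saturation near
58,000) with mirror-symmetric rounded-rectangle lung fields and a medial
ventricle square. Defaults place the cardiac frequency at 1.25 Hz (75
beats/min), perfusion amplitudes at 300 pixel-value units per lung against
a 30,000 baseline with noise SD 100 — amplitudes a fraction of a percent of
baseline, as in real perfusion-induced pixel-value changes — and a residual
respiratory drift of 150 units at 0.2 Hz, since breath-hold suppresses but
does not eliminate the respiratory component. The cardiac waveform is a
sinusoid by default with an optional fast-upstroke (second-harmonic)
variant for robustness checks. A 128 × 128 test-scale grid covering the
same field of view keeps desk runs fast; full scale is supported.

Not emulated: anatomical texture, rib and diaphragm structure, cardiac-motion
artifacts at the heart border, scatter and beam hardening, gravity-dependent
perfusion gradients, and patient motion. Passing recovery tests therefore
demonstrate that the estimator chain is correct under its own signal model —
not that the method is robust to structured clinical confounds, which the
anti-phase ventricle overlap in real images makes material (left-sided
measurements are the harder case).

The cohort simulator draws resections from a realistic lobectomy mix,
preoperative function as a fraction of predicted normal, and a true
affected-side BFR centred slightly below the side's segment share (tumours
hypoperfuse). Measured postoperative values equal the perfusion-weighted
prediction times `(1 + N(0, 0.10))` — a 10% relative spirometry error —
and respiratory complications follow
`logit(p) = 2.0 - 0.055 x ppo%DLco`, chosen so risk falls across the
<40 / 40–60 / ≥60 bands with a gradient of roughly one-half to one-fifth;
cardiovascular complications are independent at 11.5%. These are fixture
calibrations that make the rate tables and t tests exercise realistic
contrasts, not clinical claims.

## Problem sizes and determinism

Tests and the acceptance script run at the 128 × 128 × 150 test scale
(single sequences in ~0.7 s), with 50 replicates for symmetric-recovery
checks, 8 seeds per rung on a four-rung amplitude ladder, 300 replicate
pixels for the noise-attenuation closed form, and 20 seeds of 52-patient
cohorts for the prediction-correlation suite. All randomness flows through
`numpy.random.default_rng` seeds carried in the parameter objects; repeated
runs are byte-identical in their CSV/JSON artifacts, and the pipeline
manifest records a SHA-256 per artifact.

## Known limitations

- The windowed-correlation definition ("frame by frame") and the Pearson
  normalization are design choices; the clinical device's exact algorithm
  is not public. The −1..1 range of the reported statistic motivates the
  Pearson form; a lag-scanning variant is deliberately out of scope.
- BFR compression at high SNR (above) means absolute agreement with
  count-based perfusion fractions should not be expected from the synthetic
  scenes; method-agreement statistics on the synthetic cohort use a
  comparator ratio with independent noise rather than a second imaging
  model.
- MaxCCv uses all frames where a full window fits; no early/late transient
  exclusion is applied.
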