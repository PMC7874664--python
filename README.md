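# dpdr — dynamic-perfusion digital radiography analysis

Dynamic chest radiography records a sequence of low-dose radiographs at high
frame rate (15 frames/s) while the patient holds their breath. With each
heartbeat, blood leaving the ventricle transiently fills the pulmonary
vasculature: perfused lung pixels darken in anti-phase with the ventricle's
brightening, and the amplitude of that cardiac-synchronous oscillation tracks
regional blood flow. `dpdr` turns such a sequence into a pulmonary perfusion
map and carries the result through to the clinical question it serves:
predicting a lung-cancer patient's postoperative lung function before
anatomic resection, without nuclear-medicine perfusion scintigraphy.

The pipeline, for users in thoracic surgery research and functional lung
imaging:

1. **Perfusion map.** Each pixel's time series is high-pass filtered
   (4th-order zero-phase Butterworth, cutoff 0.85 Hz) to remove respiratory
   drift. A ventricle region of interest gives the reference heartbeat
   waveform `PC_lv(t)`; for every lung-field pixel the cross-correlation
   value `CCv(x, y, t)` is the Pearson correlation between `-PC_lv` and the
   filtered pixel series `PC_lf(x, y, ·)` over a sliding window of one
   cardiac period. The per-pixel maximum over frames, `MaxCCv`, is the
   perfusion image.
2. **Blood-flow ratio (BFR).** `MaxCCv` is summed over each lung field;
   the affected side's ratio is
   `BFR = SumMaxCCv_affected / (SumMaxCCv_left + SumMaxCCv_right)`.
3. **Predicted postoperative (ppo) function.** With the 19-segment lung
   model (right 3 + 2 + 5, left 3 + 2 + 4),

       ppoFEV1_seg  = preFEV1 x (19 - resected) / 19
       ppoFEV1_perf = preFEV1 x (BFR_intact + remaining/total_affected x BFR_affected)

   and the same formulas for DLco. Percent-of-predicted values are banded
   into surgical risk strata (ppo%FEV1 <40 / 40–70 / ≥70; ppo%DLco
   <40 / 40–60 / ≥60).
4. **Agreement statistics.** Pearson correlation and regression, Bland–Altman
   analysis with mean-difference ± 2 SD limits of agreement and a
   proportional-error regression, the unpaired two-tailed t test, and
   complication-rate tables by risk band.

No patient imaging is bundled. A synthetic-data module generates radiograph
sequences with known ground-truth perfusion asymmetry and surgical cohorts
with known prediction-error structure, so every stage is tested against
quantities that are known exactly.

## Worked example

```python
from dpdr import (SynthImagingParams, generate_sequence, extract_ventricle_signal,
                  compute_ccv, sum_max_ccv, blood_flow_ratio, ppo_perfusion,
                  ppo_segment_counting, percent_predicted, risk_band)

params = SynthImagingParams.test_scale(
    perfusion_amplitude_left=180.0,   # hypoperfused (affected) left lung
    perfusion_amplitude_right=300.0,
    rng_seed=1,
)
seq, masks, truth = generate_sequence(params)
cardiac = extract_ventricle_signal(seq, masks)
pmap = compute_ccv(seq, cardiac, masks)
bfr = blood_flow_ratio(sum_max_ccv(pmap, masks), affected_side="left")
print(f"cardiac frequency : {cardiac.frequency_hz:.2f} Hz "
      f"(period {cardiac.estimated_period_frames} frames, window {pmap.window_frames})")
print(f"true left fraction: {truth.true_left_fraction:.3f}")
print(f"measured BFR left : {bfr.bfr_affected:.3f}")

ppo_seg = ppo_segment_counting(1.9, "left_lower")
ppo_pw = ppo_perfusion(1.9, bfr, "left_lower")
pct = percent_predicted(ppo_pw, 2.5)
print(f"ppoFEV1 segment   : {ppo_seg:.3f} L")
print(f"ppoFEV1 perfusion : {ppo_pw:.3f} L  ({pct:.1f}% of predicted normal, "
      f"band {risk_band(pct, pct)[0]})")
```

prints

```
cardiac frequency : 1.25 Hz (period 12 frames, window 13)
true left fraction: 0.375
measured BFR left : 0.491
ppoFEV1 segment   : 1.500 L
ppoFEV1 perfusion : 1.486 L  (59.4% of predicted normal, band 40-70)
```

The estimated heart rate (1.25 Hz, 12 frames at 15 fps) sets the
correlation window. The injected left lung carries 37.5% of the oscillation
amplitude, and the recovered left BFR of 0.491 sits below 0.5 on the correct
side: because `MaxCCv` measures waveform similarity rather than amplitude,
the ratio is a monotone but compressed readout of the asymmetry (see
`docs/methods.md`). A preoperative FEV1 of 1.9 L before a left lower
lobectomy (4 of 19 segments) gives a segment-counting prediction of 1.500 L;
perfusion weighting shifts it to 1.486 L because the affected lung carries
slightly less than its anatomic share of flow. At a predicted-normal FEV1 of
2.5 L that is 59.4%, in the intermediate 40–70 risk band.

The same chain runs from the shell:

```sh
dpdr run --config examples/demo.yaml         # simulate -> map -> bfr -> ppo -> agree
dpdr simulate --out-dir run/                 # or stage by stage
dpdr perfmap --input run/seq.tif --masks run/masks.tif --out run/map.tif
dpdr bfr --map run/map.tif --masks run/masks.tif --affected left --out run/bfr.json
```

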