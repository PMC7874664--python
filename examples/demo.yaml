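# Desk-scale demonstration run: simulate a 128 x 128 breath-hold sequence with
# a hypoperfused left lung, map perfusion, compute the blood-flow ratio, then
# generate a 52-patient cohort and its agreement statistics.
out_dir: demo_run
seed: 1
imaging:
  perfusion_amplitude_left: 180.0   # left lung at 60% of the right amplitude
  perfusion_amplitude_right: 300.0
affected_side: left
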