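# Full pipeline: simulate a small cohort, run all three detectors, evaluate.
seed: 42
outdir: pulseqc_out
simulate:
  n_participants: 3
  errors:
    spike_rate: 0.025
    drop_rate: 0.025
    dilution_rate: 0.02
smoothing:
  window: 5
  kind: mean
  log_hormones: [insulin, GH]
detectors: [tukey, stepwise, em]
tukey:
  k: 3
  center: median
stepwise:
  lower_z: -3
  upper_z: 4
  glucose_floor: 2.8
  cross_sum: -8
em:
  threshold: 0.9
evaluate:
  pair: [glucose, insulin]
  max_lag: 120
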