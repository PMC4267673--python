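# Full characterization run: three RBS constructs, study design defaults.
seed: 42
design:
  t_end_min: 840
  dt_min: 10
  replicates: 6
  constructs:
    - [strong, 1.0]
    - [medium, 0.3]
    - [weak, 0.03]
noise:
  od_sd: 0.002
  fluor_cv: 0.05
steady_state:
  window_points: 5
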