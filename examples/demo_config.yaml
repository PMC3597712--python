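# Demo run configuration: simulate a cohort first, e.g.
#   eegstates simulate --out demo_cohort --n-subjects 4 --seed 1
#   eegstates all --config examples/demo_config.yaml
clustering:
  damping: 0.9
  max_iter: 1000
  conv_window: 50
  seed: 0
  jitter: 1.0e-10
  stage2_radius_factor: 4.0
  stage2_size_exponent: 0.25
  reassign: true
segmentation:
  window_s: 0.7
  overlap_fraction: 0.5
  m: 2
  p: 1
  ridge: 1.0e-08
  embed_rate_hz: 40.0
  normalize: true
  analysis_rate_hz: 128.0
  window_len: null
  tau: null
resampling:
  n_perm: 300
  n_boot: 300
  seed: 0
spectra:
  band_lo: 1.0
  band_hi: 30.0
  window_s: 2.0
manifest: demo_cohort/manifest.tsv
out_dir: demo_run
jobs: 1
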