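# Example pipeline configuration for `memdecode <stage> --config config.yaml`.
# Any key omitted falls back to the defaults in memdecode.cli.DEFAULT_CONFIG.

region: itc            # itc | hc
n_images: 200
n_units: 200
nback_levels: [1, 2, 4, 8, 32, 48, 64, 192]
nback_base_count: 24   # realized count per core level; extremes get half
mb_bins: 10            # memorability bins for pseudoimage alignment
vigor_window: [300, 500]    # ms after stimulus onset
decode_window: [300, 500]
tuning_window: [100, 500]
n_folds: 10
n_perm: 2000           # label permutations for the slope-difference test
n_boot: 2000           # bootstrap resamples for CIs
threshold_fractions: [0.0, 0.2, 0.4, 0.6, 0.8, 0.9, 1.0]
theta_step: 1.0        # degrees, plane sweep resolution
stages:
  simulate: true
  screen: true
  assemble: true
  vigor: true
  decode: true
  tuning: true
  threshold_sweep: true
  plane: true
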