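# Four synthetic cohorts emulating the four stimulation/recording
# combinations of the in vivo experiment (stimulated striatal terminal
# field -> recorded cortex), with responsive fractions set to the published
# proportions.  Run:
#   loopmapper run --config examples/open_loop_demo.yaml --seed 1 --out scratch/demo
seed: 1
stages: [simulate_spikes, psth_classify, ztests]
protocol:
  pattern: constant
  train_duration: 1.0
  n_trials: 30
  inter_trial_interval: 4.0
criterion:
  k_up: 3.0
  k_down: 1.0
  latency_window_ms: [5, 35]
psth:
  kernel_sigma_ms: 2.0
  baseline_s: 1.0
cohorts:
  - {name: DLS_to_M1,   n_units: 60, responsive_fraction: 0.24,
     baseline_rate: 5.0, rate_delta: 80.0, latency_ms_range: [8, 28]}
  - {name: VS_to_M1,    n_units: 60, responsive_fraction: 0.12,
     baseline_rate: 5.0, rate_delta: 80.0, latency_ms_range: [8, 28]}
  - {name: DLS_to_mPFC, n_units: 60, responsive_fraction: 0.03,
     baseline_rate: 5.0, rate_delta: 80.0, latency_ms_range: [8, 28]}
  - {name: VS_to_mPFC,  n_units: 60, responsive_fraction: 0.35,
     baseline_rate: 5.0, rate_delta: 80.0, latency_ms_range: [8, 28]}
ztest_pairs:
  - [DLS_to_M1, VS_to_M1]
  - [VS_to_M1, DLS_to_mPFC]
  - [DLS_to_mPFC, VS_to_mPFC]
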