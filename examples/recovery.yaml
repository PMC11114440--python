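# Planted-hub recovery scenario: two groups differing in hub coupling at
# Fz-beta, Pz-gamma (strong in controls) and O1-gamma (strong in patients).
seed: 1
simulate:
  n_per_group: {control: 15, patient: 15}
  duration_s: 60          # 10 analysis epochs; use 600 for study-scale runs
  strong_coupling: 0.85
  weak_coupling: 0.15
  common_source_gain: 1.0
  noise_gain: 1.0
  bprs: {mean: 50, sd: 12, rho: 0.0}
preprocess:
  filter_order: 4000
  window: hamming
  epoch_len_s: 5
  drop_edge_epochs: true
  notch_enabled: false
stats:
  alpha: 0.05
  q_threshold: 0.05
  top_edge_fraction: 0.2
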