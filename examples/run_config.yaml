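# Full-pipeline configuration for `serialdep run --config examples/run_config.yaml`.
sim:
  n_participants: 21
  n_trials: 400
  alpha_by_condition: {no_load: 0.92, low: 1.38, high: 1.49}
  w_true: 0.05
  noise_sd: 6.3
  lapse_rate: 0.02
  bias_terms: [[1.0, 2.0, 0.0]]
  pc_by_load: {low: 0.899, high: 0.744}
  max_step: 40
  rt_params: [0.3, 0.35]
  slow_rt_rate: 0.0
  seed: 0
lapse_cutoff: 45.0
iqr_k: 1.5
rt_cutoff: 10.0
residualize_window: 10.0
smooth_window: 10.0
n_perm: 1000
n_boot: 1000
seed: 0
output_dir: null
make_figures: false
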