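# Generative parameters for a simulated dual-task orientation experiment.
# Field names match serialdep.SimConfig.
n_participants: 21
n_trials: 400
alpha_by_condition:
  no_load: 0.92
  low: 1.38
  high: 1.49
w_true: 0.05
noise_sd: 6.3
lapse_rate: 0.02
bias_terms:
  - [1.0, 2.0, 0.0]   # amplitude (deg), frequency (cycles per 180 deg), phase (rad)
pc_by_load:
  low: 0.899
  high: 0.744
max_step: 40
rt_params: [0.3, 0.35]  # lognormal mu, sigma (seconds)
slow_rt_rate: 0.0
seed: 0
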