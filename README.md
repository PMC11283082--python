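# serialdep

Serial-dependence analysis for orientation-reproduction experiments, in
particular dual-task designs that manipulate visual working-memory (VWM)
load on alternating trials.

In a delayed orientation-reproduction task, observers rotate a probe to
match the orientation of a briefly shown stimulus. Their reports are
systematically attracted toward the stimulus seen on the previous trial
("serial dependence"). `serialdep` implements the standard analysis
battery for such data — circular error computation, multi-stage trial
cleaning, first-derivative-of-Gaussian (δoG) bias-curve fitting,
permutation and bootstrap inference, and load-conditioned comparisons —
together with a synthetic observer generator that makes every stage of
the pipeline verifiable by parameter recovery.

## The model

Orientations live on a 180° circle. For trial *n* with stimulus θₙ and
report *r*ₙ, the signed error and the stimulus-history variable are the
acute circular differences

```
error = ((r − θ) + 90) mod 180 − 90            ∈ [−90, 90)
Δ     = ((θₙ₋₁ − θₙ) + 90) mod 180 − 90        ∈ [−90, 90)
```

Serial dependence is modelled as a first derivative of a Gaussian in Δ:

```
error(Δ) = Δ · α · w · c · exp(−(wΔ)²),      c = √2·e¹ᐟ² ≈ 2.3316
```

where the half-amplitude α (degrees) is the **peak bias** toward the
previous stimulus (α > 0 = attraction, α < 0 = repulsion) and w
(1/degrees) is the inverse curve width; the constant c makes the curve's
extremum, at |Δ| = 1/(w√2), exactly equal α. The fit minimises the sum
of squared residuals on aggregate data under bounds α ∈ [−20, 20],
w ∈ [0.01, 0.1], starting from a documented search grid.

Inference is nonparametric: α (and w) are tested against zero by
refitting after randomly flipping the sign of every trial's error
("sign shuffle"), and condition differences by refitting after shuffling
condition labels, with p = (r + 1)/(N + 1). Report precision ("error
scatter", the SD of errors after removing systematic and serial biases)
is compared across load conditions with paired t-tests, Cohen's d and a
JZS Bayes factor (Cauchy prior, scale 0.707, one-tailed in the observed
direction).

Before fitting, trials pass a cleaning cascade: |error| > 45° lapses are
dropped; errors are demeaned per participant; orientation-dependent
systematic biases are removed with a sum of six sinusoids; interquartile
outliers are flagged per load condition (1.5·IQR quartile rule); and
trials slower than 10 s are excluded.

## Worked example

```python
import serialdep as sd

config = sd.SimConfig(seed=0)                      # 21 participants x 400 trials
trials = sd.generate_dataset(config)
cleaned = sd.preprocess(trials)
print(f"excluded {cleaned.exclusion_fraction:.1%} of {cleaned.n_trials} trials")

split = sd.split_conditions(cleaned)
for name in ("no_load", "load"):
    sub = split[name]
    fit = sd.fit_dog(sub["delta"].to_numpy(), sub["error_clean"].to_numpy())
    perm = sd.sign_shuffle_test(
        sub["delta"].to_numpy(), sub["error_clean"].to_numpy(),
        n_perm=10000, seed=1,
    )
    print(f"{name:8s} alpha = {fit.alpha:5.2f} deg  w = {fit.w:.3f}  "
          f"p_perm = {perm['alpha'].p_value:.4f}  (n = {fit.n_trials})")

diff = sd.label_shuffle_difference(
    split["no_load"]["delta"].to_numpy(), split["no_load"]["error_clean"].to_numpy(),
    split["load"]["delta"].to_numpy(), split["load"]["error_clean"].to_numpy(),
    n_perm=10000, seed=2,
)
print(f"alpha difference (no_load - load) = {diff['alpha_diff'].observed:.2f} deg, "
      f"p_perm = {diff['alpha_diff'].p_value:.4f}")
```

prints

```
excluded 2.8% of 8400 trials
no_load  alpha =  0.80 deg  w = 0.074  p_perm = 0.0003  (n = 4065)
load     alpha =  1.35 deg  w = 0.051  p_perm = 0.0001  (n = 4081)
alpha difference (no_load - load) = -0.55 deg, p_perm = 0.0246
```

The simulated observer was generated with α = 0.92° on single-task
(no-load) trials and α = 1.38°/1.49° on low/high-load trials; the pooled
fits recover these amplitudes, both are individually significant under
the sign-shuffle null, and the no-load-vs-load label shuffle detects the
injected difference.

The same pipeline is available from the shell:

```
serialdep simulate --config examples/sim_config.yaml --out trials.csv
serialdep preprocess --input trials.csv --out cleaned.csv
serialdep fit --input cleaned.csv
serialdep run --config examples/run_config.yaml --out results_dir --figures
serialdep reproduce-zenodo --path deposit.csv --column-map map.yaml --out results_dir
```

`run` writes a self-describing `report.json` (fits, permutation p-values,
scatter comparisons, exclusion counts, seeds and the full configuration
echo), per-condition folded-error display curves, and optional figures.
`reproduce-zenodo` applies the identical pipeline to a locally downloaded
trial-level dataset, with a YAML column map absorbing foreign headers.

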