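# Methods

This note documents the statistical model, the synthetic observer, and
the numerical and design choices behind `serialdep`.

## Circular error arithmetic

Orientations are points on a 180°-periodic circle. Signed errors and the
history variable Δ (previous minus current stimulus orientation) are
acute circular differences mapped to [−90, 90) via
`((x + 90) mod 180) − 90`. The boundary convention is forced by the
formula: a difference of exactly ±90° maps to −90°. Positive Δ together
with positive error means the report moved toward the previous stimulus,
so a positive fitted half-amplitude reads as attraction.

## The δoG bias curve

The serial bias is modelled as the first derivative of a Gaussian,

error(Δ) = Δ · α · w · c · exp(−(wΔ)²),

an odd function of Δ peaking at |Δ| = 1/(w√2). The normalising constant
is chosen as c = √2·e^{1/2} ≈ 2.3316 so that the curve's peak equals α
exactly — α is then interpretable as the peak bias in degrees. c is a
single named constant (`serialdep.DOG_C`) and can be overridden in
`dog_curve` / `DoGFitter` if a different normalisation is wanted.

**Fitting.** The fit minimises the sum of squared residuals subject to
α ∈ [−20, 20] and w ∈ [0.01, 0.1]. Because the curve is linear in α, the
amplitude is profiled out in closed form (clipped to its bounds) and the
problem reduces to a bounded one-dimensional search over w: the profiled
objective is evaluated on a fine grid (181 points, step 5·10⁻⁴) and
refined by Brent's method in the bracket around the grid minimum
(`xatol = 1e-10`). This is deterministic, recovers noiseless synthetic
parameters to ~1e-9, and agrees with a multi-start bounded quasi-Newton
fit of the raw two-parameter problem (cross-checked in the test suite).
A coarse initialisation grid (α from −4 to 4 in steps of 1, w from 0.01
to 0.1 in steps of 0.01) is also evaluated and reported as
`init_grid_best` for diagnostics. The profiled formulation makes refits
cheap (~0.5 ms at n ≈ 2000), which the permutation machinery exploits:
`DoGFitter` precomputes the width-grid design for a fixed Δ vector, and
a `weights` argument implements subset masks (label shuffles) and
multiplicity weights (bootstrap) without rebuilding it.

**Identifiability.** With |Δ| restricted to ≤ 40° by the design, small w
values are weakly identified and α and w trade off; fits can touch the w
bounds on noisy subsets while the fitted curve itself remains stable.
Parameter-level assertions in the tests therefore target realistic
sample sizes (thousands of trials), where the trade-off is mild.

## Cleaning cascade

Per participant, in order:

1. raw errors and Δ are computed for every trial (Δ from the previous
   trial's stimulus, regardless of that trial's exclusion status — the
   previous stimulus was displayed either way; only each participant's
   first trial lacks Δ);
2. |error| > 45° ⇒ lapse (treated as a guess);
3. remaining errors are demeaned per participant;
4. systematic orientation-dependent biases are removed by a sum of six
   sinusoids (below), and residuals re-centred per participant — the
   sinusoid basis has no DC term but is not exactly orthogonal to a
   constant on finite samples, so re-centring keeps the per-participant
   mean at zero to machine precision;
5. interquartile outliers are flagged per participant within each
   current-trial load condition: outside
   [q1 − 1.5·IQR, q3 + 1.5·IQR], with quartiles computed by linear
   interpolation (`numpy.percentile` default);
6. response times > 10 s are excluded.

A trial carries exactly one primary exclusion reason with precedence
lapse > iqr_outlier > slow_rt > no_previous. The reported exclusion
fraction counts lapse/IQR/RT removals only; first trials are merely
unusable for Δ-based analyses. On simulations with the default
generator, the cascade removes ≈ 2–3% of trials, comfortably below the
15% budget typical of this paradigm.

**Sum-of-six-sinusoids bias model.** The model is
Σᵢ aᵢ·sin(bᵢθ + cᵢ) with free amplitudes, frequencies and phases,
fitted by trust-region least squares. Initialisation is deterministic:
a least-squares periodogram over candidate frequencies (0.5–18 cycles
per 180°) seeds the six dominant components. With fewer than 50 trials
the 18-parameter fit is skipped and residuals pass through unchanged;
if the optimiser ever worsened the residual sum of squares the zero
model is used instead.

**Scope of the bias fit.** The sinusoid fit is pooled across
participants by default, mirroring the aggregate δoG fit. We initially
fitted it per participant, but an 18-parameter adaptive-frequency model
on ~400 trials absorbs a measurable share (~8%) of the serial-dependence
signal through incidental overfitting, attenuating recovered
half-amplitudes by ≈ 0.1°; pooling (18 parameters on thousands of
trials) removes the attenuation while still capturing shared systematic
biases such as oblique effects. `preprocess(bias_scope="per_participant")`
restores the per-observer variant for data with strongly idiosyncratic
biases. A residual ≈ 0.05–0.1° attenuation from the IQR truncation step
(asymmetric tail removal around a biased conditional mean) is inherent
to the quartile rule and affects any pipeline using it.

## Permutation and bootstrap inference

Sign shuffling multiplies every error by an independent fair ±1 and
refits; since the δoG is odd, error signs are exchangeable under the
no-bias null. Label shuffling reassigns condition labels at the trial
level, preserving group sizes, and refits both groups. Both use the
add-one convention p = (r + 1)/(N + 1) with a two-sided comparison
(|surrogate| ≥ |observed|) by default and one-sided options. Surrogate
refits run through the identical grid-initialised bounded fit as the
observed statistic, keeping null and observed values exchangeable.
Bootstrap intervals are 2.5/97.5 percentile intervals over refits of
with-replacement trial resamples. Every routine is bit-reproducible from
(data, seed, N).

Calibration at the 5% level and power for condition differences of the
size typical in load manipulations (≈ 0.8° on ~4000 trials per
condition) are verified by Monte-Carlo in the acceptance tests.

## Condition splits and error scatter

The alternating design means single-task (no-load) trials always follow
a load trial, and load trials always follow a no-load trial. The
analysis therefore splits included trials into: current no-load trials
by the previous trial's load level (prev_low / prev_high), current load
trials by their own level (curr_low / curr_high), and the two pooled
sets. The four fine subsets are disjoint by construction.

Error scatter — the precision measure — is the per-participant SD of
cleaned errors after additionally residualizing the serial-dependence
component, so that a pure bias change cannot masquerade as a precision
change. Residualization subtracts a moving-average fit of error against
Δ: each trial's local mean over trials within ± window/2 degrees of its
Δ (circular distance; `window` is the full boxcar span, default 10°).
The smoother is not an orthogonal projection, so variance reduction
holds statistically rather than pointwise, and a second smoothing pass
of the residuals is small but not identically zero. The window is a
configuration parameter; 10° captures a w = 0.05 δoG curve with < 0.06°
RMS error while removing little noise variance.

Scatter is computed per participant per current-trial condition and
compared at the group level with two-tailed paired t-tests, Cohen's
d = mean(diff)/sd(diff), and a JZS Bayes factor.

## JZS Bayes factor

BF₁₀ is computed as the ratio of the marginal likelihood of the t
statistic under a Cauchy(0, r = 0.707) prior on the standardized effect
size (noncentral-t likelihood, integrated numerically with the integral
split at the likelihood mode) to the central-t likelihood. Directed
tests truncate the prior to the half-line of the observed effect
direction (doubling its density), per the convention of one-tailed BF in
the direction of the effect; a zero observed difference falls back to
the two-sided prior. The two-sided integral matches `pingouin`'s
implementation to ~1e-10 relative error (test-suite cross-check); the
two halves average exactly to the two-sided value. Identical paired
samples return t = 0, d = 0, p = 1 with BF₁₀ < 1; constant non-zero
differences raise an error rather than returning an infinite statistic.

## Synthetic observer

The generator produces the data-generating structure the analysis
assumes, with defaults chosen to mimic a realistic experiment of this
kind:

- **Design**: 21 participants × 400 trials (10 blocks), trials in
  no-load/load pairs (no-load first), load level an independent fair
  low/high draw — so load-level splits cannot be anticipated.
- **Stimuli**: integer orientations 1–180°, first trial uniform, each
  subsequent orientation uniform within ± 40° (`max_step`) of its
  predecessor on the wrapped circle. This symmetric random walk has the
  uniform distribution as its stationary marginal, and Δ is approximately
  uniform on [−40, 40].
- **Reports**: θ + systematic bias + δoG serial bias + Gaussian noise,
  wrapped to [0, 180). The systematic bias is a configurable sum of
  sinusoids of θ (default: one 1° term with a 90° period, an
  oblique-style bias). The serial term uses the previous trial's
  stimulus and the half-amplitude of the current trial's condition
  (defaults 0.92 / 1.38 / 1.49° for no-load / low / high, w = 0.05);
  trial 1 has none. Adjustment noise defaults to 6.3° SD.
- **Lapses**: with probability 0.02 the report is uniform on the
  orientation circle; the table marks injected lapses (`is_lapse`) so
  tests can compare the > 45° subset against the lapse flags.
- **RT**: lognormal (μ = 0.3, σ = 0.35, mean ≈ 1.5 s), with an optional
  injected fraction of > 10 s trials to exercise the RT filter.
- **Memory task**: Bernoulli per-condition accuracies (defaults 0.899
  low, 0.744 high).

All randomness flows from the configuration seed through per-participant
substreams drawn in a fixed order, so identical configurations produce
bit-identical tables, and the alpha-sign symmetry of the δoG is exact in
the noise-free case.

**What the generator does not emulate** — and hence what passing
recovery tests do not show about real data: sequential dependencies
beyond one trial back, non-Gaussian or heteroscedastic report noise,
fatigue/learning drifts across blocks, response-time dependence on
error, stimulus-specific memory interactions beyond a flat Bernoulli
accuracy, and repulsive adaptation at large Δ. The generator validates
the estimator and its inference machinery, not the psychology.

## Problem sizes used in the validation suite

Monte-Carlo checks run at the scale the statistics require while staying
desk-sized: parameter recovery uses ten replicate 21 × 400 experiments;
null calibration uses 200 datasets of 2000 trials with 1000 permutations
each; power analysis uses 50 replicates of 4000 trials per condition
with 500 permutations; large-sample consistency uses a single 200 000
trial observer. The acceptance script runs the full pipeline at the
default experiment size with N = 10 000 permutations.

## Known limitations

- The δoG fit is aggregate-only; no hierarchical per-participant model.
- With |Δ| ≤ 40° designs, w is weakly identified near its lower bound.
- The folded curves are display summaries; all inference uses unfolded
  errors.
- `reproduce-zenodo` assumes a trial-level CSV; its column map handles
  renaming but not structural rearrangements (e.g. wide-format files).
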