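"""Synthetic observers for dual-task orientation-reproduction experiments.

Emulates the generative structure the analysis assumes: each participant
sees a sequence of orientations (integer degrees 1..180, consecutive
stimuli no more than ``max_step`` degrees apart on the 180-degree circle),
with a memory (load) task on every second trial whose level (low/high) is
random.  Reports are the stimulus plus

* a systematic orientation-dependent bias (sum of sinusoids),
* a serial bias following the DoG curve of the previous-trial stimulus
  difference, with a condition-specific half-amplitude,
* Gaussian adjustment noise,

wrapped into [0, 180); with probability ``lapse_rate`` the report is
instead uniform on the orientation circle.  Response times are lognormal
(with an optional injected fraction of >10 s trials) and memory responses
are Bernoulli with a per-load-level accuracy.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dog import dog_curve
from .preprocessing import compute_delta

__all__ = [
    "SimConfig",
    "generate_orientation_sequence",
    "simulate_observer",
    "generate_dataset",
]

CONDITIONS = ("no_load", "low", "high")


@dataclass
class SimConfig:
    """Generative parameters for a simulated experiment.

    Defaults mirror the no-load/low/high half-amplitudes, adjustment
    noise, memory accuracies and design structure of a 21-participant,
    400-trial orientation-reproduction experiment with alternating load
    trials.
    """

    n_participants: int = 21
    n_trials: int = 400           # must be even: trials come in no-load/load pairs
    alpha_by_condition: dict = field(
        default_factory=lambda: {"no_load": 0.92, "low": 1.38, "high": 1.49}
    )  # degrees, DoG half-amplitude per current-trial condition
    w_true: float = 0.05          # 1/degrees
    noise_sd: float = 6.3         # degrees
    lapse_rate: float = 0.02
    bias_terms: list = field(default_factory=lambda: [(1.0, 2.0, 0.0)])
    # (amplitude degrees, frequency cycles-per-180deg, phase rad); the default
    # single term with a 90-degree period emulates an oblique-style bias
    pc_by_load: dict = field(default_factory=lambda: {"low": 0.899, "high": 0.744})
    max_step: float = 40.0        # degrees, consecutive-stimulus constraint
    rt_params: tuple = (0.3, 0.35)  # lognormal (mu, sigma) of RT in seconds
    slow_rt_rate: float = 0.0     # fraction of trials forced above 10 s
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.n_trials < 2 or self.n_trials % 2:
            raise ValueError("n_trials must be even and >= 2 (no-load/load pairs)")
        if not 0.01 <= self.w_true <= 0.1:
            raise ValueError("w_true must lie in [0.01, 0.1]")
        if not 0.0 <= self.lapse_rate < 0.5:
            raise ValueError("lapse_rate must lie in [0, 0.5)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 < self.max_step <= 90:
            raise ValueError("max_step must lie in (0, 90]")
        if set(self.alpha_by_condition) != set(CONDITIONS):
            raise ValueError(f"alpha_by_condition must have keys {CONDITIONS}")
        for lvl in ("low", "high"):
            pc = self.pc_by_load.get(lvl)
            if pc is None or not 0 < pc <= 1:
                raise ValueError("pc_by_load must map low/high to values in (0, 1]")
        if not 0.0 <= self.slow_rt_rate < 1.0:
            raise ValueError("slow_rt_rate must lie in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bias_terms"] = [list(t) for t in self.bias_terms]
        d["rt_params"] = list(self.rt_params)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "bias_terms" in d:
            d["bias_terms"] = [tuple(t) for t in d["bias_terms"]]
        if "rt_params" in d:
            d["rt_params"] = tuple(d["rt_params"])
        return cls(**d)


def generate_orientation_sequence(n: int, max_step: float = 40.0, seed: int = 0):
    """Random orientation sequence (integer degrees 1..180) with a step bound.

    Consecutive orientations differ by at most ``max_step`` degrees of
    acute circular distance.  The first orientation is uniform on 1..180
    and each next one is uniform within +-``max_step`` of its predecessor
    (wrapped), which leaves the marginal distribution uniform.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < max_step <= 90:
        raise ValueError("max_step must lie in (0, 90]")
    rng = np.random.default_rng(seed)
    m = int(max_step)
    out = np.empty(n, dtype=int)
    out[0] = rng.integers(1, 181)
    steps = rng.integers(-m, m + 1, size=n - 1) if n > 1 else []
    for i, s in enumerate(steps, start=1):
        out[i] = (out[i - 1] - 1 + s) % 180 + 1
    return out


def _systematic_bias(theta, bias_terms):
    theta = np.asarray(theta, dtype=float)
    out = np.zeros_like(theta)
    for amp, freq, phase in bias_terms:
        out += amp * np.sin(2.0 * np.pi * freq * theta / 180.0 + phase)
    return out


def simulate_observer(
    theta_sequence,
    condition_labels,
    config: SimConfig,
    participant_seed: int,
) -> pd.DataFrame:
    """Simulate one observer's reports, RTs and memory responses.

    The serial-bias term on trial ``t > 1`` is the DoG curve evaluated at
    ``delta_t`` (previous minus current stimulus) with the half-amplitude
    of the current trial's condition; trial 1 has no serial term.
    Deterministic given ``participant_seed``.
    """
    theta = np.asarray(theta_sequence, dtype=float)
    labels = np.asarray(condition_labels, dtype=object)
    if theta.shape != labels.shape:
        raise ValueError("theta_sequence and condition_labels must have equal length")
    unknown = set(labels) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown condition labels: {sorted(unknown)}")
    n = theta.size
    rng = np.random.default_rng(participant_seed)

    # draw all random vectors in a fixed order so masks never shift streams
    noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else np.zeros(n)
    lapse_draw = rng.random(n)
    lapse_report = rng.uniform(0.0, 180.0, size=n)
    mu, sigma = config.rt_params
    rt = rng.lognormal(mean=mu, sigma=sigma, size=n)
    slow_draw = rng.random(n)
    slow_extra = rng.exponential(2.0, size=n)
    mem_draw = rng.random(n)

    delta = np.zeros(n)
    if n > 1:
        delta[1:] = compute_delta(theta[:-1], theta[1:])
    alpha = np.array([config.alpha_by_condition[l] for l in labels], dtype=float)
    serial = np.zeros(n)
    if n > 1:
        serial[1:] = [
            dog_curve(d, a, config.w_true) for d, a in zip(delta[1:], alpha[1:])
        ]

    reported = np.mod(theta + _systematic_bias(theta, config.bias_terms) + serial + noise, 180.0)
    is_lapse = lapse_draw < config.lapse_rate
    reported[is_lapse] = lapse_report[is_lapse]

    slow = slow_draw < config.slow_rt_rate
    rt = np.where(slow, 10.0 + slow_extra, rt)

    memory_correct = np.full(n, pd.NA, dtype=object)
    for lvl in ("low", "high"):
        sel = labels == lvl
        memory_correct[sel] = mem_draw[sel] < config.pc_by_load[lvl]

    return pd.DataFrame(
        {
            "reported": reported,
            "rt": rt,
            "memory_correct": pd.array(memory_correct, dtype="boolean"),
            "is_lapse": is_lapse,
        }
    )


def generate_dataset(config: SimConfig) -> pd.DataFrame:
    """Generate a full trial table (one row per trial, all participants).

    Trials alternate no-load (odd trial indices) and load (even indices);
    the load level on load trials is an independent fair draw between low
    and high.  Deterministic given ``config.seed``.
    """
    root = np.random.default_rng(config.seed)
    seeds = root.integers(0, 2**31 - 1, size=(config.n_participants, 3))
    block_size = max(1, config.n_trials // 10)

    frames = []
    for p in range(config.n_participants):
        seq_seed, label_seed, obs_seed = (int(s) for s in seeds[p])
        theta = generate_orientation_sequence(
            config.n_trials, config.max_step, seed=seq_seed
        )
        label_rng = np.random.default_rng(label_seed)
        levels = label_rng.choice(["low", "high"], size=config.n_trials // 2)
        labels = np.empty(config.n_trials, dtype=object)
        labels[0::2] = "no_load"
        labels[1::2] = levels
        obs = simulate_observer(theta, labels, config, participant_seed=obs_seed)
        idx = np.arange(1, config.n_trials + 1)
        frames.append(
            pd.DataFrame(
                {
                    "participant": p + 1,
                    "trial_index": idx,
                    "block": (idx - 1) // block_size + 1,
                    "has_load": labels != "no_load",
                    "load_level": np.where(labels == "no_load", "none", labels),
                    "theta": theta.astype(float),
                    "reported": obs["reported"].to_numpy(),
                    "rt": obs["rt"].to_numpy(),
                    "memory_correct": obs["memory_correct"],
                    "is_lapse": obs["is_lapse"].to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
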