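"""Condition splitting, residualized error scatter and group comparisons.

The alternating dual-task design yields four fine condition subsets plus
two pooled ones:

* current no-load trials split by the **previous** trial's load level
  (``prev_low`` / ``prev_high``) — single-task trials whose history load
  varied;
* current load trials split by the **current** level
  (``curr_low`` / ``curr_high``) — dual-task trials;
* pooled ``no_load`` and ``load``.

Error scatter is the per-participant standard deviation of cleaned
errors after additionally residualizing the serial-dependence component
(a circular moving-average fit of error against delta), so that a pure
bias change cannot masquerade as a precision change.

Group comparisons are paired two-tailed t-tests with Cohen's d
(mean/sd of the paired differences) and a JZS Bayes factor (Cauchy prior
on effect size, scale 0.707), one-tailed in the direction of the
observed effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .preprocessing import CleanedSeries

__all__ = [
    "ConditionSplit",
    "GroupTest",
    "split_conditions",
    "residualize_history",
    "error_scatter",
    "paired_comparison",
    "jzs_bf10",
]

RESIDUALIZE_WINDOW = 10.0  # degrees; boxcar half-width of the delta smoother


@dataclass
class ConditionSplit:
    """Disjoint fine subsets plus pooled no-load/load trial tables."""

    subsets: dict = field(default_factory=dict)

    @property
    def counts(self) -> dict:
        return {k: len(v) for k, v in self.subsets.items()}

    def __getitem__(self, key: str) -> pd.DataFrame:
        return self.subsets[key]


def split_conditions(series: CleanedSeries) -> ConditionSplit:
    """Partition included trials (with defined delta) per the design scheme."""
    d = series.included()
    for col in ("has_load", "load_level", "prev_load_level"):
        if col not in d.columns:
            raise ValueError(f"cleaned series is missing condition tag {col!r}")
    no_load = d[~d["has_load"]]
    load = d[d["has_load"]]
    return ConditionSplit(
        subsets={
            "prev_low": no_load[no_load["prev_load_level"] == "low"],
            "prev_high": no_load[no_load["prev_load_level"] == "high"],
            "curr_low": load[load["load_level"] == "low"],
            "curr_high": load[load["load_level"] == "high"],
            "no_load": no_load,
            "load": load,
        }
    )


def residualize_history(deltas, errors, window: float = RESIDUALIZE_WINDOW):
    """Remove the serial-dependence component by a moving-average fit in delta.

    For each trial, subtract the mean error of all trials whose delta lies
    within ``window / 2`` degrees (circular distance in the 180-degree
    delta space), i.e. ``window`` is the full boxcar span.  Returns the
    residual errors.
    """
    if not window > 0:
        raise ValueError("window must be positive")
    d = np.asarray(deltas, dtype=float).ravel()
    e = np.asarray(errors, dtype=float).ravel()
    if d.shape != e.shape:
        raise ValueError("deltas and errors must have the same length")
    if d.size == 0:
        return e.copy()
    dist = np.abs(np.mod(d[:, None] - d[None, :] + 90.0, 180.0) - 90.0)
    near = dist <= window / 2.0
    ma = (near @ e) / near.sum(axis=1)
    return e - ma


def error_scatter(
    series: CleanedSeries,
    window: float = RESIDUALIZE_WINDOW,
    conditions: tuple = ("no_load", "low", "high", "load"),
) -> pd.DataFrame:
    """Per-participant SD of serial-residualized cleaned errors per condition.

    Residualization is applied within each participant x current-trial
    condition cell.  ``load`` pools the low and high cells (residualized
    separately, per the per-condition convention).  Returns a tidy frame
    with columns ``participant, condition, scatter, n``.
    """
    d = series.included()
    rows = []
    for pid, grp in d.groupby("participant", sort=True):
        resid_by_level = {}
        for lvl, sub in grp.groupby("load_level", sort=False):
            resid_by_level[lvl] = pd.Series(
                residualize_history(
                    sub["delta"].to_numpy(), sub["error_clean"].to_numpy(), window
                ),
                index=sub.index,
            )
        for cond in conditions:
            if cond == "no_load":
                vals = resid_by_level.get("none")
            elif cond == "load":
                parts = [resid_by_level[k] for k in ("low", "high") if k in resid_by_level]
                vals = pd.concat(parts) if parts else None
            else:
                vals = resid_by_level.get(cond)
            if vals is None or len(vals) < 2:
                rows.append({"participant": pid, "condition": cond,
                             "scatter": np.nan, "n": 0 if vals is None else len(vals)})
                continue
            rows.append(
                {
                    "participant": pid,
                    "condition": cond,
                    "scatter": float(np.std(vals, ddof=1)),
                    "n": len(vals),
                }
            )
    return pd.DataFrame(rows)


def jzs_bf10(
    t: float, n: int, r: float = 0.707, alternative: str = "two-sided"
) -> float:
    """JZS Bayes factor for a one-sample / paired t statistic.

    ``BF10 = integral of the noncentral-t likelihood under a Cauchy(0, r)
    prior on the standardized effect size, divided by the central-t
    likelihood``.  ``alternative`` 'greater'/'less' truncates the prior to
    positive/negative effects (doubling its density on that half-line).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    nu = n - 1
    sqn = np.sqrt(n)

    def lik(delta):
        return stats.nct.pdf(t, nu, delta * sqn)

    def prior(delta):
        return stats.cauchy.pdf(delta, 0.0, r)

    peak = t / sqn  # likelihood mode; split the integral there for accuracy
    if alternative == "two-sided":
        pieces = [(-np.inf, min(0.0, peak)), (min(0.0, peak), max(0.0, peak)),
                  (max(0.0, peak), np.inf)]
        scale = 1.0
    elif alternative == "greater":
        pieces = [(0.0, max(peak, 1.0)), (max(peak, 1.0), np.inf)]
        scale = 2.0
    elif alternative == "less":
        pieces = [(-np.inf, min(peak, -1.0)), (min(peak, -1.0), 0.0)]
        scale = 2.0
    else:
        raise ValueError(f"unknown alternative {alternative!r}")

    num = 0.0
    for a, b in pieces:
        if a == b:
            continue
        val, _ = integrate.quad(lambda x: lik(x) * prior(x) * scale, a, b, limit=200)
        num += val
    den = stats.t.pdf(t, nu)
    return float(num / den)


@dataclass(frozen=True)
class GroupTest:
    """Paired comparison: t statistic, Cohen's d and a directed JZS BF10."""

    t: float
    df: int
    p: float
    d: float
    bf10: float
    direction: str  # 'greater' | 'less' | 'two-sided' (zero observed effect)

    def to_dict(self) -> dict:
        return {"t": self.t, "df": self.df, "p": self.p, "d": self.d,
                "bf10": self.bf10, "direction": self.direction}


def paired_comparison(values_a, values_b, bf_scale: float = 0.707) -> GroupTest:
    """Two-tailed paired t-test with Cohen's d and a direction-tailed JZS BF10.

    ``d = mean(diff) / sd(diff)``.  The Bayes factor is one-tailed in the
    direction of the observed mean difference (two-sided when it is zero).
    Raises ``ValueError`` for constant non-zero differences (t undefined).
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    diff = a - b
    n = diff.size
    sd = float(np.std(diff, ddof=1))
    mean = float(diff.mean())
    if sd == 0.0:
        if mean == 0.0:  # identical samples: a well-defined null result
            return GroupTest(
                t=0.0, df=n - 1, p=1.0, d=0.0,
                bf10=jzs_bf10(0.0, n, bf_scale, "two-sided"),
                direction="two-sided",
            )
        raise ValueError(
            "paired differences have zero variance but non-zero mean; "
            "the t statistic is undefined"
        )
    tstat, p = stats.ttest_rel(a, b)
    d = mean / sd
    direction = "greater" if mean > 0 else "less"
    bf = jzs_bf10(float(tstat), n, bf_scale, direction)
    return GroupTest(
        t=float(tstat), df=n - 1, p=float(p), d=float(d), bf10=float(bf),
        direction=direction,
    )
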