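"""Permutation and bootstrap inference for DoG serial-dependence fits.

Two surrogate-null schemes:

* **sign shuffle** — each surrogate multiplies every trial's error by an
  independent fair +-1 and refits; tests a single condition's parameters
  against zero (the DoG is odd, so under the no-bias null the error signs
  are exchangeable);
* **label shuffle** — surrogates randomly reassign condition labels
  between two trial sets (preserving group sizes), refit both and record
  the parameter differences.

p-values use the add-one convention ``p = (r + 1) / (n_perm + 1)`` where
``r`` counts surrogates at least as extreme as the observation; the
default is two-sided (``|surrogate| >= |observed|``).  Surrogate refits
use the identical grid-initialised bounded fit as the observed statistic,
so null and observed values are exchangeable.  Bootstrap intervals are
percentile intervals over refits of trial resamples (with replacement).
All routines are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dog import DoGFitter

__all__ = [
    "PermutationResult",
    "BootstrapResult",
    "sign_shuffle_test",
    "label_shuffle_difference",
    "bootstrap_params",
]

_MAX_REDRAWS = 100


@dataclass
class PermutationResult:
    statistic_name: str   # alpha | w | alpha_diff | w_diff
    observed: float
    surrogates: np.ndarray
    n_perm: int
    p_value: float
    seed: int
    alternative: str = "two-sided"
    n_redrawn: int = 0

    def to_dict(self, keep_surrogates: bool = False) -> dict:
        d = {
            "statistic": self.statistic_name,
            "observed": self.observed,
            "n_perm": self.n_perm,
            "p_value": self.p_value,
            "seed": self.seed,
            "alternative": self.alternative,
            "n_redrawn": self.n_redrawn,
        }
        if keep_surrogates:
            d["surrogates"] = [float(v) for v in self.surrogates]
        return d


@dataclass
class BootstrapResult:
    alpha_interval: tuple
    w_interval: tuple
    alphas: np.ndarray
    ws: np.ndarray
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "alpha_ci": [float(v) for v in self.alpha_interval],
            "w_ci": [float(v) for v in self.w_interval],
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def _perm_p(observed: float, surrogates: np.ndarray, alternative: str) -> float:
    if alternative == "two-sided":
        r = int(np.count_nonzero(np.abs(surrogates) >= abs(observed)))
    elif alternative == "greater":
        r = int(np.count_nonzero(surrogates >= observed))
    elif alternative == "less":
        r = int(np.count_nonzero(surrogates <= observed))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (r + 1) / (surrogates.size + 1)


def _check(deltas, errors, n_perm):
    deltas = np.asarray(deltas, dtype=float).ravel()
    errors = np.asarray(errors, dtype=float).ravel()
    if deltas.shape != errors.shape:
        raise ValueError("deltas and errors must have the same length")
    ok = np.isfinite(deltas) & np.isfinite(errors)
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    return deltas[ok], errors[ok]


def sign_shuffle_test(
    deltas,
    errors,
    n_perm: int = 10000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> dict:
    """Test the fitted (alpha, w) of one condition against the sign-shuffle null.

    Returns ``{"alpha": PermutationResult, "w": PermutationResult}``.
    """
    deltas, errors = _check(deltas, errors, n_perm)
    fitter = DoGFitter(deltas)
    obs = fitter.fit(errors)
    rng = np.random.default_rng(seed)
    sa = np.empty(n_perm)
    sw = np.empty(n_perm)
    n_redrawn = 0
    i = 0
    while i < n_perm:
        signs = rng.integers(0, 2, size=errors.size) * 2 - 1
        fit = fitter.fit(signs * errors)
        if not fit.converged and n_redrawn < _MAX_REDRAWS:
            n_redrawn += 1
            continue
        sa[i], sw[i] = fit.alpha, fit.w
        i += 1
    return {
        "alpha": PermutationResult(
            "alpha", obs.alpha, sa, n_perm, _perm_p(obs.alpha, sa, alternative),
            seed, alternative, n_redrawn,
        ),
        "w": PermutationResult(
            "w", obs.w, sw, n_perm, _perm_p(obs.w, sw, alternative),
            seed, alternative, n_redrawn,
        ),
    }


def label_shuffle_difference(
    deltas_a,
    errors_a,
    deltas_b,
    errors_b,
    n_perm: int = 10000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> dict:
    """Test parameter differences (a minus b) between two conditions.

    Surrogates reassign condition labels at the trial level, preserving
    group sizes.  Returns ``{"alpha_diff": ..., "w_diff": ...}``.
    """
    da, ea = _check(deltas_a, errors_a, n_perm)
    db, eb = _check(deltas_b, errors_b, n_perm)
    if da.size == 0 or db.size == 0:
        raise ValueError("both trial sets must be non-empty")
    d = np.concatenate([da, db])
    e = np.concatenate([ea, eb])
    na = da.size
    fitter = DoGFitter(d)
    mask_a = np.zeros(d.size)
    mask_a[:na] = 1.0
    fa = fitter.fit(e, weights=mask_a)
    fb = fitter.fit(e, weights=1.0 - mask_a)
    obs_da, obs_dw = fa.alpha - fb.alpha, fa.w - fb.w

    rng = np.random.default_rng(seed)
    sda = np.empty(n_perm)
    sdw = np.empty(n_perm)
    n_redrawn = 0
    i = 0
    while i < n_perm:
        perm = rng.permutation(d.size)
        m = np.zeros(d.size)
        m[perm[:na]] = 1.0
        ga = fitter.fit(e, weights=m)
        gb = fitter.fit(e, weights=1.0 - m)
        if not (ga.converged and gb.converged) and n_redrawn < _MAX_REDRAWS:
            n_redrawn += 1
            continue
        sda[i] = ga.alpha - gb.alpha
        sdw[i] = ga.w - gb.w
        i += 1
    return {
        "alpha_diff": PermutationResult(
            "alpha_diff", obs_da, sda, n_perm,
            _perm_p(obs_da, sda, alternative), seed, alternative, n_redrawn,
        ),
        "w_diff": PermutationResult(
            "w_diff", obs_dw, sdw, n_perm,
            _perm_p(obs_dw, sdw, alternative), seed, alternative, n_redrawn,
        ),
    }


def bootstrap_params(
    deltas,
    errors,
    n_boot: int = 1000,
    seed: int = 0,
    ci: tuple = (2.5, 97.5),
) -> BootstrapResult:
    """Percentile bootstrap intervals for (alpha, w): resample trials with replacement."""
    deltas, errors = _check(deltas, errors, max(n_boot, 100))
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    n = deltas.size
    fitter = DoGFitter(deltas)
    rng = np.random.default_rng(seed)
    alphas = np.empty(n_boot)
    ws = np.empty(n_boot)
    p = np.full(n, 1.0 / n)
    for i in range(n_boot):
        counts = rng.multinomial(n, p).astype(float)
        fit = fitter.fit(errors, weights=counts)
        alphas[i], ws[i] = fit.alpha, fit.w
    a_lo, a_hi = np.percentile(alphas, ci)
    w_lo, w_hi = np.percentile(ws, ci)
    return BootstrapResult(
        alpha_interval=(float(a_lo), float(a_hi)),
        w_interval=(float(w_lo), float(w_hi)),
        alphas=alphas,
        ws=ws,
        n_boot=n_boot,
        seed=seed,
    )
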