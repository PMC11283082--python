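"""First-derivative-of-Gaussian (DoG) model of serial dependence.

The attraction of an orientation report toward the stimulus seen on the
previous trial is modelled as an odd, bell-flanked tuning curve of the
acute stimulus difference ``delta`` (previous minus current, degrees)::

    bias(delta) = delta * alpha * w * c * exp(-(w * delta)**2)

``alpha`` is the half-amplitude in degrees (positive = attraction,
negative = repulsion) and ``w`` the inverse curve width in 1/degrees.
The constant ``c = sqrt(2) * exp(1/2)`` normalises the curve so that its
extremum, attained at ``|delta| = 1 / (w * sqrt(2))``, equals ``alpha``
exactly — i.e. ``alpha`` is the peak bias in degrees.

Fitting minimises the sum of squared residuals under box constraints
``alpha in [-20, 20]``, ``w in [0.01, 0.1]``.  Because the curve is
linear in ``alpha``, the amplitude is profiled out in closed form and
the optimisation reduces to a one-dimensional bounded search over ``w``
(fine grid plus Brent refinement).  :class:`DoGFitter` precomputes the
width-grid design for a fixed set of deltas so that permutation and
bootstrap loops can refit cheaply via the ``weights`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "DOG_C",
    "ALPHA_BOUNDS",
    "W_BOUNDS",
    "DoGFit",
    "DoGFitter",
    "dog_curve",
    "dog_peak",
    "fit_dog",
]

#: Amplitude-normalising constant: makes the curve's peak equal ``alpha``.
DOG_C: float = float(np.sqrt(2.0) * np.exp(0.5))

#: Fit bounds for the half-amplitude (degrees) and inverse width (1/degrees).
ALPHA_BOUNDS: tuple[float, float] = (-20.0, 20.0)
W_BOUNDS: tuple[float, float] = (0.01, 0.1)

# Initialisation search grid: alpha in -4..4 step 1, w in 0.01..0.1 step 0.01.
_INIT_ALPHA_GRID = np.arange(-4.0, 4.0 + 0.5, 1.0)
_INIT_W_GRID = np.linspace(0.01, 0.10, 10)

# Fine profile grid over w (step 5e-4); indices 0,20,...,180 coincide with
# the coarse initialisation grid above.
_N_W_GRID = 181

# Above this many basis-matrix entries the design is evaluated row by row
# instead of being materialised (memory guard for very large fits).
_DENSE_LIMIT = 4_000_000


def dog_curve(delta, alpha: float, w: float, c: float = DOG_C):
    """Evaluate the DoG serial-bias curve at ``delta`` (degrees).

    Odd in ``delta``; peak value ``alpha`` at ``|delta| = dog_peak(w)``.
    """
    if not w > 0:
        raise ValueError(f"w must be positive, got {w!r}")
    delta = np.asarray(delta, dtype=float)
    return delta * alpha * w * c * np.exp(-((w * delta) ** 2))


def dog_peak(w: float) -> float:
    """Return the ``|delta|`` at which ``|dog_curve|`` is maximal: 1/(w*sqrt(2))."""
    if not w > 0:
        raise ValueError(f"w must be positive, got {w!r}")
    return 1.0 / (w * np.sqrt(2.0))


def _basis(delta, w, c: float = DOG_C):
    """DoG curve with unit amplitude: dog_curve(delta, 1, w)."""
    return delta * w * c * np.exp(-((w * delta) ** 2))


@dataclass(frozen=True)
class DoGFit:
    """Result of a bounded least-squares DoG fit."""

    alpha: float          # half-amplitude, degrees
    w: float              # inverse width, 1/degrees
    c: float              # normalising constant used
    sse: float            # sum of squared residuals, degrees^2
    n_trials: int
    converged: bool
    init_grid_best: tuple[float, float]  # (alpha0, w0) best coarse grid point

    def predict(self, delta):
        return dog_curve(delta, self.alpha, self.w, self.c)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "w": self.w,
            "c": self.c,
            "sse": self.sse,
            "n_trials": self.n_trials,
            "converged": self.converged,
            "init_alpha": self.init_grid_best[0],
            "init_w": self.init_grid_best[1],
            "alpha_bounds": list(ALPHA_BOUNDS),
            "w_bounds": list(W_BOUNDS),
        }


class DoGFitter:
    """Repeated bounded DoG fits on a fixed vector of deltas.

    Parameters
    ----------
    deltas
        Acute orientation differences (degrees), previous minus current.
    alpha_bounds, w_bounds
        Box constraints of the minimisation.
    c
        Amplitude-normalising constant (see :data:`DOG_C`).

    Notes
    -----
    The basis ``g_w(delta)`` is precomputed on a fine grid of widths, so a
    refit for sign-flipped errors, a subset mask, or bootstrap multiplicities
    costs two matrix–vector products plus a 1-D refinement.
    """

    def __init__(
        self,
        deltas,
        alpha_bounds: tuple[float, float] = ALPHA_BOUNDS,
        w_bounds: tuple[float, float] = W_BOUNDS,
        c: float = DOG_C,
        n_w: int = _N_W_GRID,
    ):
        deltas = np.asarray(deltas, dtype=float).ravel()
        if deltas.size == 0:
            raise ValueError("deltas must be non-empty")
        if not np.all(np.isfinite(deltas)):
            raise ValueError("deltas must be finite")
        self.deltas = deltas
        self.alpha_bounds = (float(alpha_bounds[0]), float(alpha_bounds[1]))
        self.w_bounds = (float(w_bounds[0]), float(w_bounds[1]))
        self.c = float(c)
        self.w_grid = np.linspace(self.w_bounds[0], self.w_bounds[1], n_w)
        # coarse-grid w values must be a subset of the fine grid
        self._coarse_idx = np.array(
            [int(np.argmin(np.abs(self.w_grid - w0))) for w0 in _INIT_W_GRID]
        )
        self._dense = deltas.size * n_w <= _DENSE_LIMIT
        if self._dense:
            G = _basis(deltas[None, :], self.w_grid[:, None], self.c)
            self._G = G
            self._G2 = G * G
            self._den0 = self._G2.sum(axis=1)

    # -- internals ---------------------------------------------------------

    def _grid_profile(self, e, weights):
        """Return (num, den, ee) per grid width: num = <g,e>_w, den = <g,g>_w."""
        if self._dense:
            if weights is None:
                num = self._G @ e
                den = self._den0
                ee = float(e @ e)
            else:
                num = self._G @ (weights * e)
                den = self._G2 @ weights
                ee = float(weights @ (e * e))
        else:
            num = np.empty_like(self.w_grid)
            den = np.empty_like(self.w_grid)
            we = e if weights is None else weights * e
            for i, wv in enumerate(self.w_grid):
                g = _basis(self.deltas, wv, self.c)
                num[i] = g @ we
                den[i] = g @ g if weights is None else (weights * g) @ g
            ee = float(e @ e) if weights is None else float(weights @ (e * e))
        return num, den, ee

    def _alpha_hat(self, num, den):
        lo, hi = self.alpha_bounds
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        return np.clip(a, lo, hi)

    # -- public API --------------------------------------------------------

    def fit(self, errors, weights=None) -> DoGFit:
        """Fit (alpha, w) by bounded least squares.

        ``weights`` (optional, non-negative) act as trial multiplicities:
        a 0/1 mask restricts the fit to a subset (label shuffles), integer
        counts implement bootstrap resampling.
        """
        e = np.asarray(errors, dtype=float).ravel()
        if e.shape != self.deltas.shape:
            raise ValueError("errors must have the same length as deltas")
        if weights is not None:
            weights = np.asarray(weights, dtype=float).ravel()
            if weights.shape != e.shape:
                raise ValueError("weights must have the same length as deltas")
            if np.any(weights < 0):
                raise ValueError("weights must be non-negative")

        num, den, ee = self._grid_profile(e, weights)
        a_hat = self._alpha_hat(num, den)
        sse_grid = ee - 2.0 * a_hat * num + a_hat**2 * den
        k = int(np.argmin(sse_grid))

        # coarse (alpha, w) initialisation grid, reported for diagnostics
        ci = self._coarse_idx
        coarse_sse = (
            ee
            - 2.0 * _INIT_ALPHA_GRID[:, None] * num[ci][None, :]
            + _INIT_ALPHA_GRID[:, None] ** 2 * den[ci][None, :]
        )
        ia, iw = np.unravel_index(int(np.argmin(coarse_sse)), coarse_sse.shape)
        init_best = (float(_INIT_ALPHA_GRID[ia]), float(self.w_grid[ci[iw]]))

        # local Brent refinement of w in the bracket around the fine-grid best
        if weights is None:
            d_sub, e_sub, w_sub = self.deltas, e, None
        else:
            nz = weights > 0
            d_sub, e_sub, w_sub = self.deltas[nz], e[nz], weights[nz]

        lo_a, hi_a = self.alpha_bounds

        def profiled(wv):
            g = _basis(d_sub, wv, self.c)
            if w_sub is None:
                num1 = float(g @ e_sub)
                den1 = float(g @ g)
            else:
                num1 = float(g @ (w_sub * e_sub))
                den1 = float((w_sub * g) @ g)
            a = num1 / den1 if den1 > 0 else 0.0
            a = min(max(a, lo_a), hi_a)
            return ee - 2.0 * a * num1 + a * a * den1, a

        lo_w = float(self.w_grid[max(k - 1, 0)])
        hi_w = float(self.w_grid[min(k + 1, self.w_grid.size - 1)])
        res = minimize_scalar(
            lambda wv: profiled(wv)[0],
            bounds=(lo_w, hi_w),
            method="bounded",
            options={"xatol": 1e-10},
        )
        converged = bool(res.success)
        sse_ref, a_ref = profiled(float(res.x))
        if sse_ref <= sse_grid[k]:
            w_best, sse_best, a_best = float(res.x), float(sse_ref), float(a_ref)
        else:  # pragma: no cover - refinement can never be worse in practice
            w_best, sse_best, a_best = (
                float(self.w_grid[k]),
                float(sse_grid[k]),
                float(a_hat[k]),
            )

        sse_best = max(sse_best, 0.0)  # guard against cancellation round-off
        n_eff = e.size if weights is None else int(round(float(weights.sum())))
        return DoGFit(
            alpha=a_best,
            w=w_best,
            c=self.c,
            sse=sse_best,
            n_trials=n_eff,
            converged=converged,
            init_grid_best=init_best,
        )


def fit_dog(deltas, errors, min_trials: int = 30, **kwargs) -> DoGFit:
    """Fit the DoG curve to (delta, error) pairs.

    Pairs with undefined (NaN) delta or error are dropped.  Raises
    ``ValueError`` if fewer than ``min_trials`` valid pairs remain.
    """
    deltas = np.asarray(deltas, dtype=float).ravel()
    errors = np.asarray(errors, dtype=float).ravel()
    if deltas.shape != errors.shape:
        raise ValueError("deltas and errors must have the same length")
    ok = np.isfinite(deltas) & np.isfinite(errors)
    deltas, errors = deltas[ok], errors[ok]
    if deltas.size < min_trials:
        raise ValueError(
            f"need at least {min_trials} valid (delta, error) pairs, got {deltas.size}"
        )
    return DoGFitter(deltas, **kwargs).fit(errors)
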