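"""Asymmetric Rescorla-Wagner model of trial-wise state self-esteem.

State self-esteem on trial ``t`` is modelled as the previous state plus an
affective prediction error (APE) -- the valence of the current social
feedback minus the previous state -- scaled by a learning rate that may
differ for positive and negative errors::

    Feeling(t) = Feeling(t-1) + alpha_pos * APE   if APE > 0
    Feeling(t) = Feeling(t-1) + alpha_neg * APE   if APE < 0
    APE        = v_feedback(t) - Feeling(t-1)

All quantities live on the visual-analogue scale [0, 1].  Because each
update is a convex move toward a value in [0, 1], trajectories are bounded
in [0, 1] for any learning rates in [0, 1].

Fitting minimises the sum of squared errors (SSE) between the observed and
modelled self-esteem time course under box constraints, from a grid of
multi-starts; one-rate and two-rate variants are compared by a Gaussian
least-squares BIC.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "RWParams",
    "RWFitResult",
    "predict_trajectory",
    "fit_rw",
    "bic",
    "updating_bias",
]

_START_GRID = (0.1, 0.5, 0.9)
_FTOL = 1e-8


@dataclass(frozen=True)
class RWParams:
    """Free parameters of the affective-updating model.

    ``prior`` is the initial (pre-task) state self-esteem; ``alpha_pos`` and
    ``alpha_neg`` are the learning rates for positive and negative affective
    prediction errors.  All three are constrained to [0, 1].
    """

    prior: float
    alpha_pos: float
    alpha_neg: float

    def __post_init__(self) -> None:
        for name in ("prior", "alpha_pos", "alpha_neg"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v!r} outside [0, 1]")

    @property
    def n_free_params(self) -> int:
        return 2 if self.alpha_pos == self.alpha_neg else 3


@dataclass
class RWFitResult:
    """Result of a bound-constrained SSE fit of the updating model."""

    params: RWParams
    sse: float
    bic: float
    n_obs: int
    predicted: np.ndarray
    n_rates: int
    converged: bool = True
    n_starts_used: int = 0
    degenerate: bool = False
    perfect_fit: bool = False

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValueError("sse must be non-negative")


def predict_trajectory(params: RWParams, v_feedback) -> np.ndarray:
    """Run the updating recursion forward over a feedback sequence.

    Returns the modelled self-esteem after each trial's feedback; the prior
    is the pre-task state and is not part of the output.
    """
    v = np.asarray(v_feedback, dtype=float)
    if v.ndim != 1:
        raise ValueError("v_feedback must be one-dimensional")
    if v.size and (np.nanmin(v) < 0.0 or np.nanmax(v) > 1.0):
        raise ValueError("feedback valence outside [0, 1]")
    return _trajectory(params.prior, params.alpha_pos, params.alpha_neg, v)


def _trajectory(prior: float, a_pos: float, a_neg: float, v: np.ndarray) -> np.ndarray:
    out = np.empty(v.shape[0])
    f = prior
    for t in range(v.shape[0]):
        ape = v[t] - f
        f = f + (a_pos if ape > 0 else a_neg) * ape
        out[t] = f
    return out


def _sse(theta, v, obs, mask, one_rate: bool) -> float:
    if one_rate:
        prior, a_pos = theta
        a_neg = a_pos
    else:
        prior, a_pos, a_neg = theta
    f = prior
    total = 0.0
    for t in range(v.shape[0]):
        ape = v[t] - f
        f = f + (a_pos if ape > 0 else a_neg) * ape
        if mask[t]:
            r = obs[t] - f
            total += r * r
    return total


def fit_rw(self_esteem, v_feedback, n_rates: int = 2) -> RWFitResult:
    """Fit the updating model to an observed self-esteem time course.

    Missing (NaN) self-esteem ratings are dropped from the SSE while the
    recursion still advances on their feedback.  With ``n_rates=1`` a single
    shared learning rate is fitted (2 free parameters); with ``n_rates=2``
    positive and negative rates are separate (3 free parameters).

    The optimiser is L-BFGS-B with [0, 1] bounds launched from every point
    of a {0.1, 0.5, 0.9}^k start grid; the best SSE wins.
    """
    if n_rates not in (1, 2):
        raise ValueError("n_rates must be 1 or 2")
    obs = np.asarray(self_esteem, dtype=float)
    v = np.asarray(v_feedback, dtype=float)
    if obs.shape != v.shape or obs.ndim != 1:
        raise ValueError("self_esteem and v_feedback must be equal-length 1-D sequences")
    mask = ~np.isnan(obs)
    n_obs = int(mask.sum())
    if obs.shape[0] < 5 or n_obs < 5:
        raise ValueError("need at least 5 observed trials")
    if np.nanmin(obs) < 0 or np.nanmax(obs) > 1 or v.min() < 0 or v.max() > 1:
        raise ValueError("values outside [0, 1]")
    k = 2 if n_rates == 1 else 3

    observed = obs[mask]
    if np.ptp(observed) == 0.0:
        # Flat series: zero learning reproduces it exactly.
        params = RWParams(prior=float(observed[0]), alpha_pos=0.0, alpha_neg=0.0)
        pred = predict_trajectory(params, v)
        sse = float(np.sum((observed - pred[mask]) ** 2))
        return RWFitResult(
            params=params, sse=sse, bic=bic(sse, n_obs, k), n_obs=n_obs,
            predicted=pred, n_rates=n_rates, degenerate=True,
            perfect_fit=(sse == 0.0),
        )

    one_rate = n_rates == 1
    bounds = [(0.0, 1.0)] * k
    best = None
    n_starts = 0
    any_converged = False
    for start in itertools.product(_START_GRID, repeat=k):
        res = minimize(
            _sse, np.asarray(start), args=(v, obs, mask, one_rate),
            method="L-BFGS-B", bounds=bounds, options={"ftol": _FTOL, "maxiter": 500},
        )
        n_starts += 1
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    theta = np.clip(best.x, 0.0, 1.0)
    if one_rate:
        params = RWParams(prior=float(theta[0]), alpha_pos=float(theta[1]),
                          alpha_neg=float(theta[1]))
    else:
        params = RWParams(prior=float(theta[0]), alpha_pos=float(theta[1]),
                          alpha_neg=float(theta[2]))
    sse = float(best.fun)
    pred = predict_trajectory(params, v)
    return RWFitResult(
        params=params, sse=sse, bic=bic(sse, n_obs, k), n_obs=n_obs,
        predicted=pred, n_rates=n_rates, converged=any_converged,
        n_starts_used=n_starts, perfect_fit=(sse == 0.0),
    )


def bic(sse: float, n_obs: int, k: int) -> float:
    """Gaussian least-squares BIC: ``n*ln(sse/n) + k*ln(n)``; lower is better.

    The noise variance is profiled out and omitted from ``k`` identically for
    every model, so only BIC differences between models are meaningful.  A
    perfect fit (``sse == 0``) returns ``-inf``.
    """
    if n_obs <= k or k < 1:
        raise ValueError("require n_obs > k >= 1")
    if sse < 0:
        raise ValueError("sse must be non-negative")
    if sse == 0.0:
        return -math.inf
    return n_obs * math.log(sse / n_obs) + k * math.log(n_obs)


def updating_bias(fit: RWFitResult) -> float:
    """Valence asymmetry of affective updating, ``alpha_pos - alpha_neg``."""
    if fit.n_rates != 2:
        raise ValueError("updating bias requires a 2-rate fit")
    return fit.params.alpha_pos - fit.params.alpha_neg
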