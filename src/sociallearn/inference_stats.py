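"""Group-level and individual-differences inference.

Paired and Welch t-tests with the effect-size conventions used for
two-group learning studies, Pearson/Spearman/partial correlations,
Fisher's z-transform, and Huber robust (IRLS) regression.

Effect-size conventions
-----------------------
Cohen's d is derived from the t statistic and sample sizes:

* independent samples (Welch):  ``d = t * sqrt(1/n1 + 1/n2)``
* paired samples:               ``d_z = |t| / sqrt(n)``

These conversions require only printed test statistics, which makes
reported effects reproducible without raw data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "DegenerateInputError",
    "TTestResult",
    "CorrelationResult",
    "RobustFitResult",
    "welch_t",
    "paired_t",
    "cohen_d_from_welch_t",
    "cohen_d_from_paired_t",
    "pearson",
    "spearman",
    "partial_correlation",
    "fisher_z",
    "robust_regression",
]


class DegenerateInputError(ValueError):
    """Input has no usable variance (or is otherwise degenerate)."""


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    d: float
    mean_diff: float
    kind: str  # "paired" | "welch"


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    kind: str  # "pearson" | "spearman" | "partial"
    n: int
    controlled_for: str | None = None


@dataclass
class RobustFitResult:
    coef: np.ndarray
    weights: np.ndarray
    scale: float
    converged: bool
    n_iter: int


def cohen_d_from_welch_t(t: float, n1: int, n2: int) -> float:
    """Independent-samples Cohen's d from a (Welch) t statistic."""
    return t * math.sqrt(1.0 / n1 + 1.0 / n2)


def cohen_d_from_paired_t(t: float, n: int) -> float:
    """Paired-samples d_z from a paired t statistic (magnitude convention)."""
    return abs(t) / math.sqrt(n)


def welch_t(x, y) -> TTestResult:
    """Welch's two-sample t-test for unequal variances, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2 or not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("each sample needs >= 2 finite values")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise DegenerateInputError("both samples have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    t = float(res.statistic)
    return TTestResult(
        t=t, df=float(res.df), p=float(res.pvalue),
        d=cohen_d_from_welch_t(t, len(x), len(y)),
        mean_diff=float(x.mean() - y.mean()), kind="welch",
    )


def paired_t(x, y) -> TTestResult:
    """Student's paired t-test on x - y, two-sided; d is the d_z convention."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("paired samples must have equal length >= 2")
    diff = x - y
    if np.ptp(diff) <= 1e-12 * max(1.0, float(np.abs(diff).max())):
        raise DegenerateInputError("paired differences have zero variance")
    res = stats.ttest_rel(x, y)
    t = float(res.statistic)
    n = len(x)
    return TTestResult(
        t=t, df=float(n - 1), p=float(res.pvalue),
        d=cohen_d_from_paired_t(t, n),
        mean_diff=float(diff.mean()), kind="paired",
    )


def pearson(x, y) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input to correlation")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), kind="pearson", n=len(x))


def spearman(x, y) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input to correlation")
    r, p = stats.spearmanr(x, y)
    return CorrelationResult(r=float(r), p=float(p), kind="spearman", n=len(x))


def partial_correlation(x, y, z, label: str = "covariate") -> CorrelationResult:
    """Pearson correlation of x and y after residualising both on z.

    Both variables are regressed on z with an intercept by OLS; the
    correlation of the residuals is tested against a t distribution with
    n - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = len(x)
    if not (len(y) == n and len(z) == n) or n < 4:
        raise ValueError("need equal-length samples, n >= 4")
    for name, v in (("x", x), ("y", y), ("z", z)):
        if np.ptp(v) == 0:
            raise DegenerateInputError(f"{name} is constant")
    Z = np.column_stack([np.ones(n), z])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    # a variable fully explained by the covariate leaves only rounding noise
    ssx, ssy = float(rx @ rx), float(ry @ ry)
    vx = float(((x - x.mean()) ** 2).sum())
    vy = float(((y - y.mean()) ** 2).sum())
    if ssx <= 1e-24 * vx or ssy <= 1e-24 * vy:
        return CorrelationResult(r=0.0, p=1.0, kind="partial", n=n, controlled_for=label)
    denom = math.sqrt(ssx * ssy)
    r = float(rx @ ry) / denom
    df = n - 3
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df)
    return CorrelationResult(r=r, p=float(p), kind="partial", n=n, controlled_for=label)


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilising transform, arctanh(r); |r| must be < 1."""
    if not abs(r) < 1.0:
        raise ValueError(f"|r| must be < 1 for Fisher z (got {r})")
    return math.atanh(r)


def robust_regression(X, y, add_intercept: bool = True,
                      family: str = "huber") -> RobustFitResult:
    """Robust linear regression by iteratively reweighted least squares.

    Huber weights (tuning constant 1.345) with MAD scale by default;
    ``family="bisquare"`` switches to Tukey's biweight (4.685).  With clean
    Gaussian data the fit is close to OLS; gross outliers are downweighted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    design = sm.add_constant(X, has_constant="add") if add_intercept else X
    if design.shape[0] < design.shape[1] + 1:
        raise ValueError("need at least one more row than columns")
    if family == "huber":
        norm = sm.robust.norms.HuberT(t=1.345)
    elif family == "bisquare":
        norm = sm.robust.norms.TukeyBiweight(c=4.685)
    else:
        raise ValueError(f"unknown family {family!r}")
    model = sm.RLM(y, design, M=norm)
    fit = model.fit(scale_est="mad", maxiter=50, tol=1e-8)
    n_iter = len(fit.fit_history.get("params", [])) or 50
    return RobustFitResult(
        coef=np.asarray(fit.params), weights=np.asarray(fit.weights),
        scale=float(fit.scale), converged=n_iter < 50, n_iter=n_iter,
    )
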