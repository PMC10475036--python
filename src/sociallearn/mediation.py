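"""Two-level mediation of trial-level feedback effects.

For each subject and each candidate mediator region, three OLS regressions
decompose the effect of the feedback mismatch X on the self-evaluation
change Y through the trial-level mediator signal M:

* path a:   M ~ X                (manipulation -> mediator)
* paths b, c': Y ~ M + X         (mediator -> outcome, and direct effect)
* path c:   Y ~ X                (total effect)

with the indirect (mediated) effect ab = a * b; for per-subject OLS on the
same trials the identity c = c' + ab holds exactly.  At the second level
each path is tested across subjects with a one-sample t-test, and the mean
indirect effect gets a bias-corrected percentile bootstrap CI (resampling
subjects), since the product term is not normally distributed.  A
significant indirect effect whose sign opposes the total effect is
classified as suppression ("activity working against the behavioural
effect") rather than mediation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TrialSeries",
    "MediationPaths",
    "PathSummary",
    "MediationGroupResult",
    "subject_paths",
    "group_mediation",
    "conjunction",
]

PATH_NAMES = ("a", "b", "ab", "c", "c_prime")


class MediationInputError(ValueError):
    pass


@dataclass(frozen=True)
class TrialSeries:
    """One subject's trial-level (X, M, Y) triplet for a single region."""

    subject_id: str
    x: np.ndarray
    m: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        m = np.asarray(self.m, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (x.shape == m.shape == y.shape) or x.ndim != 1 or x.shape[0] < 8:
            raise MediationInputError("x, m, y must be equal-length 1-D, length >= 8")
        if not (np.isfinite(x).all() and np.isfinite(m).all() and np.isfinite(y).all()):
            raise MediationInputError("non-finite values in trial series")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "y", y)


@dataclass(frozen=True)
class MediationPaths:
    subject_id: str
    a: float
    b: float
    c: float
    c_prime: float

    @property
    def ab(self) -> float:
        return self.a * self.b


@dataclass(frozen=True)
class PathSummary:
    mean: float
    t: float
    df: float
    p: float


@dataclass
class MediationGroupResult:
    paths: dict                      # name -> PathSummary
    ab_ci: tuple                     # bias-corrected bootstrap CI for mean ab
    classification: str              # "mediation" | "suppression" | "none"
    n_subjects: int
    n_boot: int
    alpha: float
    subject_paths: list = field(default_factory=list)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise MediationInputError("cannot standardize a constant series")
    return (v - v.mean()) / sd


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, y, rcond=None)[0]


def subject_paths(series: TrialSeries, standardize: bool = True) -> MediationPaths:
    """First-level path coefficients for one subject (OLS with intercepts).

    With ``standardize`` (default), x, m and y are z-scored within subject
    so path coefficients are comparable across subjects.
    """
    x, m, y = series.x, series.m, series.y
    if np.ptp(x) == 0:
        raise MediationInputError("constant x")
    if np.ptp(m) == 0 or np.ptp(y) == 0:
        raise MediationInputError("constant m or y")
    if standardize:
        x, m, y = _zscore(x), _zscore(m), _zscore(y)
    n = x.shape[0]
    one = np.ones(n)
    a = _ols(np.column_stack([one, x]), m)[1]
    bc = _ols(np.column_stack([one, m, x]), y)
    c = _ols(np.column_stack([one, x]), y)[1]
    return MediationPaths(subject_id=series.subject_id, a=float(a),
                          b=float(bc[1]), c=float(c), c_prime=float(bc[2]))


def _bc_bootstrap_ci(values: np.ndarray, n_boot: int, alpha: float,
                     rng) -> tuple:
    """Bias-corrected percentile bootstrap CI for the mean of ``values``."""
    n = values.shape[0]
    obs = values.mean()
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = values[idx].mean(axis=1)
    prop = np.mean(boot < obs)
    # guard the probit at the extremes
    prop = min(max(prop, 1.0 / (n_boot + 1)), 1.0 - 1.0 / (n_boot + 1))
    z0 = stats.norm.ppf(prop)
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    lo_q = stats.norm.cdf(2 * z0 - zcrit)
    hi_q = stats.norm.cdf(2 * z0 + zcrit)
    return (float(np.quantile(boot, lo_q)), float(np.quantile(boot, hi_q)))


def group_mediation(all_series, n_boot: int = 5000, seed: int | None = None,
                    alpha: float = 0.05, standardize: bool = True) -> MediationGroupResult:
    """Second-level (across-subjects) mediation inference for one region.

    One-sample t-tests on each path's per-subject coefficients; a
    bias-corrected percentile bootstrap CI for the mean indirect effect
    (``n_boot=0`` skips the bootstrap and reports a degenerate CI).
    """
    per_subject = [subject_paths(s, standardize=standardize) for s in all_series]
    if len(per_subject) < 3:
        raise MediationInputError("need at least 3 subjects with valid paths")
    n = len(per_subject)
    arrays = {
        "a": np.array([p.a for p in per_subject]),
        "b": np.array([p.b for p in per_subject]),
        "ab": np.array([p.ab for p in per_subject]),
        "c": np.array([p.c for p in per_subject]),
        "c_prime": np.array([p.c_prime for p in per_subject]),
    }
    summaries = {}
    for name in PATH_NAMES:
        v = arrays[name]
        if np.ptp(v) == 0:
            t, p = (0.0, 1.0) if v.mean() == 0 else (np.inf, 0.0)
        else:
            res = stats.ttest_1samp(v, 0.0)
            t, p = float(res.statistic), float(res.pvalue)
        summaries[name] = PathSummary(mean=float(v.mean()), t=t, df=float(n - 1), p=p)

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        ci = _bc_bootstrap_ci(arrays["ab"], n_boot, alpha, rng)
    else:
        m = float(arrays["ab"].mean())
        ci = (m, m)

    ab, c = summaries["ab"], summaries["c"]
    if ab.p < alpha:
        classification = ("suppression"
                          if np.sign(ab.mean) != np.sign(c.mean) and ab.mean != 0
                          else "mediation")
    else:
        classification = "none"
    return MediationGroupResult(
        paths=summaries, ab_ci=ci, classification=classification,
        n_subjects=n, n_boot=n_boot, alpha=alpha, subject_paths=per_subject,
    )


def conjunction(results, alpha: float = 0.05, require_sign: int = 0) -> list:
    """Indices of regions significant on paths a, b and ab simultaneously.

    ``results`` is a sequence of :class:`MediationGroupResult`, one per
    region.  ``require_sign`` of +1/-1 additionally requires the mean ab to
    have that sign (0 accepts either).
    """
    hits = []
    for idx, res in enumerate(results):
        ok = all(res.paths[name].p < alpha for name in ("a", "b", "ab"))
        if ok and require_sign != 0:
            ok = np.sign(res.paths["ab"].mean) == require_sign
        if ok:
            hits.append(idx)
    return hits


def series_from_trials(trials, region: int, standardize_input: bool = False):
    """Build per-subject :class:`TrialSeries` from a tidy cohort table.

    X is the feedback mismatch, M the region's mediator amplitude, Y the
    T2 - T1 self-evaluation change (standardization happens downstream).
    """
    col = f"mediator_{region}"
    out = []
    for sid, sub in trials.groupby("subject_id", sort=False):
        x = sub["delta_eval"].to_numpy(dtype=float)
        m = sub[col].to_numpy(dtype=float)
        y = (sub["self_eval_t2"].to_numpy(dtype=float)
             - sub["self_eval_t1_val"].to_numpy(dtype=float))
        out.append(TrialSeries(subject_id=str(sid), x=x, m=m, y=y))
    return out
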