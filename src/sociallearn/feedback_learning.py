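"""Valence-split estimation of social influence on self-evaluation.

The T2 re-evaluation of each cue is modelled as the T1 self-evaluation plus
the feedback mismatch, weighted separately for positive and negative
mismatch::

    SelfEval(T2) = SelfEval(T1) + beta_pos * dEval   (dEval > 0)
    SelfEval(T2) = SelfEval(T1) + beta_neg * dEval   (dEval < 0)

Per subject this is an ordinary least-squares regression of the change
``T2 - T1`` on the two sign-gated mismatch regressors (no intercept by
default, mirroring the model above).  The "social influence bias" is
``beta_pos - beta_neg``: positive values mean the subject moved more toward
favourable than unfavourable feedback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_cohort import Cohort

__all__ = ["EstimationError", "LearningBetas", "fit_valence_betas", "cohort_betas"]


class EstimationError(ValueError):
    """Per-subject estimation failed (too few trials of a sign, rank deficiency)."""


@dataclass(frozen=True)
class LearningBetas:
    subject_id: str
    beta_pos: float
    beta_neg: float
    n_pos_trials: int
    n_neg_trials: int
    residual_sd: float
    intercept: float = 0.0

    @property
    def bias(self) -> float:
        """Social influence bias, ``beta_pos - beta_neg`` (exact)."""
        return self.beta_pos - self.beta_neg


def fit_valence_betas(subject: pd.DataFrame, include_intercept: bool = False) -> LearningBetas:
    """OLS fit of the valence-split influence model for one subject.

    ``subject`` is that subject's slice of the tidy trial table (columns
    ``self_eval_t1_val``, ``self_eval_t2``, ``delta_eval``; ``subject_id``
    optional).  Zero-mismatch trials carry no valence information and are
    excluded.  Requires at least 2 trials of each mismatch sign.
    """
    sid = str(subject["subject_id"].iloc[0]) if "subject_id" in subject else ""
    delta = subject["delta_eval"].to_numpy(dtype=float)
    y = (subject["self_eval_t2"].to_numpy(dtype=float)
         - subject["self_eval_t1_val"].to_numpy(dtype=float))
    keep = delta != 0.0
    ok = keep & ~np.isnan(y)
    delta, y = delta[ok], y[ok]
    n_pos = int((delta > 0).sum())
    n_neg = int((delta < 0).sum())
    if n_pos < 2:
        raise EstimationError(f"subject {sid or '?'}: fewer than 2 positive-mismatch trials")
    if n_neg < 2:
        raise EstimationError(f"subject {sid or '?'}: fewer than 2 negative-mismatch trials")

    cols = [delta * (delta > 0), delta * (delta < 0)]
    if include_intercept:
        cols.append(np.ones_like(delta))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise EstimationError(f"subject {sid or '?'}: rank-deficient design")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(len(y) - X.shape[1], 1)
    return LearningBetas(
        subject_id=sid,
        beta_pos=float(coef[0]), beta_neg=float(coef[1]),
        n_pos_trials=n_pos, n_neg_trials=n_neg,
        residual_sd=float(np.sqrt(resid @ resid / dof)),
        intercept=float(coef[2]) if include_intercept else 0.0,
    )


def cohort_betas(cohort: Cohort | pd.DataFrame, include_intercept: bool = False) -> pd.DataFrame:
    """First-level betas for every subject; one row per subject.

    Group labels are carried through for second-level tests.  Per-subject
    estimation errors are re-raised with the subject id attached.
    """
    trials = cohort.trials if isinstance(cohort, Cohort) else cohort
    rows = []
    for sid, sub in trials.groupby("subject_id", sort=False):
        try:
            b = fit_valence_betas(sub, include_intercept=include_intercept)
        except EstimationError as err:
            raise EstimationError(f"subject {sid}: {err}") from err
        rows.append({
            "subject_id": sid,
            "group": sub["group"].iloc[0] if "group" in sub else "",
            "beta_pos": b.beta_pos, "beta_neg": b.beta_neg, "bias": b.bias,
            "n_pos_trials": b.n_pos_trials, "n_neg_trials": b.n_neg_trials,
            "residual_sd": b.residual_sd, "intercept": b.intercept,
        })
    return pd.DataFrame(rows)
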