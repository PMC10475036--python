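"""Parameter-recovery, model-selection and calibration suites.

These simulations are the package's evidence that the estimation pipeline
identifies the generating process: noise-free identifiability, recovery of
the valence biases under realistic rating noise, BIC discrimination of the
1- vs 2-rate updating model, calibration and coverage of the multilevel
mediation inference, and power for the group-by-valence interaction at the
study's sample sizes.  Every routine is deterministic given its seed.
"""

from __future__ import annotations

import numpy as np

from .affective_updating import fit_rw, updating_bias
from .feedback_learning import cohort_betas, fit_valence_betas
from .inference_stats import welch_t
from .mediation import group_mediation, series_from_trials, subject_paths
from .synthetic_cohort import (GeneratorConfig, SubjectParams,
                               generate_cohort, simulate_subject)

__all__ = [
    "noise_free_identifiability",
    "bias_recovery",
    "bic_model_selection",
    "mediation_null_calibration",
    "mediation_ab_coverage",
    "interaction_power",
]


def _derive_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31))


def noise_free_identifiability(seed: int = 0) -> dict:
    """Max absolute recovery error per parameter on a zero-noise cohort.

    With every noise source silenced both first-level models are exactly
    identified, so errors should be at numerical-optimization precision.
    """
    cfg = GeneratorConfig(rating_noise_sd=0.0, esteem_noise_sd=0.0,
                          t2_noise_sd=0.0, mediator_to_vas=0.0, seed=seed)
    cohort = generate_cohort(cfg)
    betas = cohort_betas(cohort).set_index("subject_id")
    errs = {k: [] for k in ("beta_pos", "beta_neg", "prior", "alpha_pos", "alpha_neg")}
    for p in cohort.ground_truth:
        sub = cohort.subject_trials(p.subject_id)
        fit = fit_rw(sub["self_esteem"].to_numpy(), sub["v_feedback"].to_numpy(),
                     n_rates=2)
        errs["beta_pos"].append(abs(betas.loc[p.subject_id, "beta_pos"] - p.beta_pos))
        errs["beta_neg"].append(abs(betas.loc[p.subject_id, "beta_neg"] - p.beta_neg))
        errs["prior"].append(abs(fit.params.prior - p.prior))
        errs["alpha_pos"].append(abs(fit.params.alpha_pos - p.alpha_pos))
        errs["alpha_neg"].append(abs(fit.params.alpha_neg - p.alpha_neg))
    return {k: float(np.max(v)) for k, v in errs.items()}


def _uniform_subject(i: int, rng, fix_alphas=None) -> SubjectParams:
    a_pos, a_neg = (fix_alphas if fix_alphas is not None
                    else rng.uniform(0, 1, 2))
    return SubjectParams(
        subject_id=f"s{i}", group="HC",
        beta_pos=float(rng.uniform()), beta_neg=float(rng.uniform()),
        prior=float(rng.uniform(0.2, 0.8)),
        alpha_pos=float(a_pos), alpha_neg=float(a_neg),
        trait_eval_mean=0.5,
    )


def bias_recovery(n_subjects: int = 100, noise_sd: float = 0.05,
                  seed: int = 0) -> dict:
    """Recovery of both valence biases under rating-scale noise.

    Subjects get betas and learning rates drawn uniformly on [0, 1];
    reports the correlation between true and recovered social-influence
    bias and the median absolute error of the affective-updating bias.
    """
    rng = np.random.default_rng(_derive_seed(seed, 1))
    cfg = GeneratorConfig(t2_noise_sd=noise_sd, esteem_noise_sd=noise_sd,
                          mediator_to_vas=0.0)
    true_inf, est_inf, alpha_err = [], [], []
    for i in range(n_subjects):
        p = _uniform_subject(i, rng)
        df = simulate_subject(p, cfg, rng)
        true_inf.append(p.beta_pos - p.beta_neg)
        est_inf.append(fit_valence_betas(df).bias)
        fit = fit_rw(df["self_esteem"].to_numpy(), df["v_feedback"].to_numpy(),
                     n_rates=2)
        alpha_err.append(abs(updating_bias(fit) - (p.alpha_pos - p.alpha_neg)))
    return {
        "influence_bias_correlation": float(np.corrcoef(true_inf, est_inf)[0, 1]),
        "influence_bias_mae": float(np.mean(np.abs(np.array(true_inf)
                                                   - np.array(est_inf)))),
        "updating_bias_median_abs_error": float(np.median(alpha_err)),
        "n_subjects": n_subjects,
    }


def bic_model_selection(n_subjects: int = 100, alphas=(0.6, 0.2),
                        noise_sd: float = 0.05, seed: int = 0) -> dict:
    """Per-subject BIC comparison of 1- vs 2-rate updating models.

    ``alphas`` fixes the generating learning rates for every subject;
    returns the percentage of subjects whose BIC prefers each variant.
    """
    rng = np.random.default_rng(_derive_seed(seed, 2))
    cfg = GeneratorConfig(esteem_noise_sd=noise_sd)
    prefer2 = 0
    for i in range(n_subjects):
        p = _uniform_subject(i, rng, fix_alphas=alphas)
        df = simulate_subject(p, cfg, rng)
        esteem = df["self_esteem"].to_numpy()
        v = df["v_feedback"].to_numpy()
        if fit_rw(esteem, v, n_rates=2).bic < fit_rw(esteem, v, n_rates=1).bic:
            prefer2 += 1
    return {
        "pct_prefer_2rate": 100.0 * prefer2 / n_subjects,
        "pct_prefer_1rate": 100.0 * (n_subjects - prefer2) / n_subjects,
        "n_subjects": n_subjects,
    }


def _mediation_cfg(a_strength: float, b_strength: float, n_sad: int,
                   n_hc: int, seed: int) -> GeneratorConfig:
    return GeneratorConfig(n_sad=n_sad, n_hc=n_hc, n_regions=1,
                           region_paths=[(a_strength, b_strength)], seed=seed)


def mediation_null_calibration(n_cohorts: int = 500, seed: int = 0) -> dict:
    """Type-I rate of the indirect-effect test with a present a-path and a
    null b-path, at the study's cohort size (21 + 23 subjects)."""
    rej = 0
    for k in range(n_cohorts):
        cfg = _mediation_cfg(0.5, 0.0, 21, 23, _derive_seed(seed, 1000 + k))
        res = group_mediation(series_from_trials(generate_cohort(cfg).trials, 1),
                              n_boot=0)
        rej += res.paths["ab"].p < 0.05
    return {"rejection_rate": rej / n_cohorts, "n_cohorts": n_cohorts}


def true_standardized_ab(a_strength: float = 0.5, b_strength: float = 0.5,
                         seed: int = 0, n_subjects: int = 300,
                         n_trials: int = 2000) -> float:
    """Monte-Carlo oracle for the population mean standardized indirect
    effect: many long-run subjects, averaged first-level paths."""
    cfg = _mediation_cfg(a_strength, b_strength, n_subjects // 2,
                         n_subjects - n_subjects // 2, _derive_seed(seed, 3))
    cfg.n_trials = n_trials
    cohort = generate_cohort(cfg)
    abs_ = [subject_paths(s).ab
            for s in series_from_trials(cohort.trials, 1)]
    return float(np.mean(abs_))


def mediation_ab_coverage(n_cohorts: int = 100, n_boot: int = 2000,
                          seed: int = 0) -> dict:
    """Bootstrap-CI coverage of the generating indirect effect.

    40-subject cohorts with a = b = 0.5; the target value is the long-run
    Monte-Carlo mean of the per-subject standardized ab.
    """
    truth = true_standardized_ab(seed=seed)
    covered, means = 0, []
    for k in range(n_cohorts):
        cfg = _mediation_cfg(0.5, 0.5, 20, 20, _derive_seed(seed, 2000 + k))
        res = group_mediation(series_from_trials(generate_cohort(cfg).trials, 1),
                              n_boot=n_boot, seed=_derive_seed(seed, 5000 + k))
        lo, hi = res.ab_ci
        covered += lo <= truth <= hi
        means.append(res.paths["ab"].mean)
    return {
        "coverage_pct": 100.0 * covered / n_cohorts,
        "true_ab": truth,
        "mean_estimated_ab": float(np.mean(means)),
        "n_cohorts": n_cohorts,
    }


def interaction_power(n_runs: int = 100, seed: int = 0) -> dict:
    """Detection rate of the group-by-valence interaction at study scale.

    Default cohorts put the SAD-like mean influence bias at -0.2 and the
    control-like at +0.2; the interaction is the Welch t on the per-subject
    bias between groups.
    """
    hits = 0
    for k in range(n_runs):
        cohort = generate_cohort(GeneratorConfig(seed=_derive_seed(seed, 4000 + k)))
        betas = cohort_betas(cohort)
        res = welch_t(betas.loc[betas["group"] == "HC", "bias"].to_numpy(),
                      betas.loc[betas["group"] == "SAD", "bias"].to_numpy())
        hits += res.p < 0.05
    return {"detection_rate_pct": 100.0 * hits / n_runs, "n_runs": n_runs}
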