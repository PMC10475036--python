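"""Synthetic cohorts for the social-feedback self-evaluation task.

Emulates a 52-trial speech-feedback paradigm: on each trial the subject
rates themself on an evaluative cue (visual-analogue scale, VAS, coded
0-1), receives judges' feedback drawn from a distribution centred on their
own rating (about half the trials more favourable than the self-rating,
half less), rates their momentary state self-esteem, and later re-rates
every cue (T2).  Two groups -- a socially-anxious-like (SAD) group and a
control-like (HC) group -- differ in the distributions of their
ground-truth learning parameters.

All ratings on negatively worded cues ("I looked anxious") are recoded to
a favourability scale (``1 - rating``) before the feedback mismatch
``delta_eval = feedback_val - self_eval_t1_val`` is formed, so that a
positive mismatch always means "the judges saw me more favourably than I
saw myself".  Raw and recoded values are both stored.

State self-esteem evolves by the asymmetric Rescorla-Wagner rule
(:mod:`sociallearn.affective_updating`); T2 re-evaluation follows the
valence-split influence model (slope ``beta_pos`` for positive mismatch,
``beta_neg`` for negative).  Per-region trial-level mediator amplitudes
``M_r = a_r * z(delta_eval) + e_r`` are attached, and the mediator noise
feeds back into the T2 outcome with weight ``b_r`` so that downstream
mediation analyses see genuine a- and b-paths with known strengths.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .affective_updating import RWParams, predict_trajectory

__all__ = [
    "ConfigError",
    "ParamDist",
    "GroupParamSpec",
    "GeneratorConfig",
    "SubjectParams",
    "Cohort",
    "generate_cohort",
    "draw_feedback",
    "simulate_subject",
    "write_cohort",
    "read_cohort",
]

GROUP_SAD = "SAD"
GROUP_HC = "HC"


class ConfigError(ValueError):
    """A generator configuration violated an invariant; names the field."""


@dataclass(frozen=True)
class ParamDist:
    """Mean/SD of a truncated-normal parameter distribution (clipped to [0,1])."""

    mean: float
    sd: float


@dataclass(frozen=True)
class GroupParamSpec:
    """Per-group distributions of the ground-truth subject parameters."""

    beta_pos: ParamDist
    beta_neg: ParamDist
    prior: ParamDist
    alpha_pos: ParamDist
    alpha_neg: ParamDist
    trait_eval: ParamDist


def _default_group_params() -> dict:
    # SAD-like: lower prior self-esteem, stronger negative than positive
    # learning; control-like the reverse.  Magnitudes are configuration.
    return {
        GROUP_SAD: GroupParamSpec(
            beta_pos=ParamDist(0.3, 0.1), beta_neg=ParamDist(0.5, 0.1),
            prior=ParamDist(0.4, 0.1), alpha_pos=ParamDist(0.2, 0.1),
            alpha_neg=ParamDist(0.4, 0.1), trait_eval=ParamDist(0.4, 0.1),
        ),
        GROUP_HC: GroupParamSpec(
            beta_pos=ParamDist(0.5, 0.1), beta_neg=ParamDist(0.3, 0.1),
            prior=ParamDist(0.6, 0.1), alpha_pos=ParamDist(0.4, 0.1),
            alpha_neg=ParamDist(0.2, 0.1), trait_eval=ParamDist(0.6, 0.1),
        ),
    }


def _default_region_paths() -> list:
    # (a_strength, b_strength) per region: a full mediator, an a-only
    # region, a b-only region, and a null region.
    return [(0.5, 0.5), (0.5, 0.0), (0.0, 0.5), (0.0, 0.0)]


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-cohort generator.

    SDs are in VAS units unless noted.  ``region_paths`` holds one
    ``(a_strength, b_strength)`` pair per mediator region in standardized
    units; ``mediator_to_vas`` converts the b-path contribution back to
    VAS units in the T2 outcome.
    """

    n_trials: int = 52
    n_sad: int = 21
    n_hc: int = 23
    mismatch_sd: float = 0.15
    rating_noise_sd: float = 0.05
    esteem_noise_sd: float = 0.05
    t2_noise_sd: float = 0.05
    n_regions: int = 4
    region_paths: list = field(default_factory=_default_region_paths)
    mediator_noise_sd: float = 1.0
    mediator_to_vas: float = 0.02
    latent_bias_corr: float = 0.3
    group_params: dict = field(default_factory=_default_group_params)
    seed: int = 0

    def violations(self) -> list:
        """Exhaustive list of invariant violations (empty when valid)."""
        errs = []
        if self.n_trials < 4:
            errs.append("n_trials: must be >= 4")
        if self.n_sad < 2:
            errs.append("n_sad: group size must be >= 2")
        if self.n_hc < 2:
            errs.append("n_hc: group size must be >= 2")
        for name in ("mismatch_sd", "rating_noise_sd", "esteem_noise_sd",
                     "t2_noise_sd", "mediator_noise_sd"):
            if getattr(self, name) < 0:
                errs.append(f"{name}: SD must be >= 0")
        if self.n_regions < 0:
            errs.append("n_regions: must be >= 0")
        if not (0.0 <= self.latent_bias_corr < 1.0):
            errs.append("latent_bias_corr: must be in [0, 1)")
        if len(self.region_paths) != self.n_regions:
            errs.append("region_paths: length must equal n_regions")
        for g in (GROUP_SAD, GROUP_HC):
            if g not in self.group_params:
                errs.append(f"group_params: missing group {g}")
                continue
            spec = self.group_params[g]
            for pname in ("beta_pos", "beta_neg", "prior", "alpha_pos", "alpha_neg",
                          "trait_eval"):
                dist = getattr(spec, pname)
                if not (0.0 <= dist.mean <= 1.0):
                    errs.append(f"group_params[{g}].{pname}.mean: must be in [0, 1]")
                if dist.sd < 0:
                    errs.append(f"group_params[{g}].{pname}.sd: must be >= 0")
        return errs

    def validate(self) -> "GeneratorConfig":
        errs = self.violations()
        if errs:
            raise ConfigError("; ".join(errs))
        return self


@dataclass(frozen=True)
class SubjectParams:
    """Ground-truth parameters of one simulated subject."""

    subject_id: str
    group: str
    beta_pos: float
    beta_neg: float
    prior: float
    alpha_pos: float
    alpha_neg: float
    trait_eval_mean: float

    def __post_init__(self) -> None:
        for name in ("prior", "alpha_pos", "alpha_neg"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v!r} outside [0, 1]")


@dataclass
class Cohort:
    """Trial-level data for all subjects plus the generating ground truth."""

    trials: pd.DataFrame
    ground_truth: list
    config: GeneratorConfig

    @property
    def subject_ids(self) -> list:
        return list(dict.fromkeys(self.trials["subject_id"]))

    def subject_trials(self, subject_id: str) -> pd.DataFrame:
        return self.trials[self.trials["subject_id"] == subject_id]


def draw_feedback(self_eval_val: float, mismatch_sd: float, rng) -> tuple:
    """Draw one judges' feedback value centred on the self-evaluation.

    The mismatch is zero-mean Gaussian with SD ``mismatch_sd``; feedback is
    clipped to the VAS bounds.  An exact-zero mismatch is redrawn once so
    trials stay sign-classifiable (guard disabled when ``mismatch_sd == 0``).
    Returns ``(feedback_val, delta_eval)``.
    """
    if not (0.0 <= self_eval_val <= 1.0):
        raise ValueError("self_eval_val outside [0, 1]")
    fb = float(np.clip(self_eval_val + rng.normal(0.0, mismatch_sd), 0.0, 1.0))
    delta = fb - self_eval_val
    if delta == 0.0 and mismatch_sd > 0.0:
        fb = float(np.clip(self_eval_val + rng.normal(0.0, mismatch_sd), 0.0, 1.0))
        delta = fb - self_eval_val
    return fb, delta


def _balanced_feedback(t1_val: np.ndarray, mismatch_sd: float, rng) -> tuple:
    """Sign-balanced feedback draws: exactly half the trials get a positive
    mismatch (magnitudes half-normal, same marginal as the unconditioned
    draw).  Clipping-induced zero mismatches are redrawn."""
    n = t1_val.shape[0]
    signs = np.concatenate([np.ones(n // 2), -np.ones(n - n // 2)])
    rng.shuffle(signs)
    fb = np.empty(n)
    for i in range(n):
        if mismatch_sd == 0.0:
            fb[i] = t1_val[i]
            continue
        s = signs[i]
        for _ in range(16):
            m = s * abs(rng.normal(0.0, mismatch_sd))
            val = float(np.clip(t1_val[i] + m, 0.0, 1.0))
            if val != t1_val[i]:
                break
            s = -s  # rating pinned at a bound: only the other sign is reachable
        fb[i] = val
    return fb, fb - t1_val


def simulate_subject(params: SubjectParams, config: GeneratorConfig, rng) -> pd.DataFrame:
    """Simulate one subject's full trial table from ground-truth parameters."""
    n = config.n_trials
    wording = np.array(["positive"] * (n // 2) + ["negative"] * (n - n // 2))
    rng.shuffle(wording)
    neg = wording == "negative"

    t1_val = np.clip(params.trait_eval_mean + rng.normal(0.0, config.rating_noise_sd, n),
                     0.0, 1.0)
    fb_val, delta = _balanced_feedback(t1_val, config.mismatch_sd, rng)

    # raw on-screen ratings: favourability recoding inverted for negative cues
    t1_raw = np.where(neg, 1.0 - t1_val, t1_val)
    fb_raw = np.where(neg, 1.0 - fb_val, fb_val)

    rw = RWParams(prior=params.prior, alpha_pos=params.alpha_pos,
                  alpha_neg=params.alpha_neg)
    esteem = np.clip(predict_trajectory(rw, fb_val)
                     + rng.normal(0.0, config.esteem_noise_sd, n), 0.0, 1.0)

    # mediators: M_r = a_r * z(delta) + e_r; e_r leaks into the T2 outcome
    # with weight b_r so the mediator carries unique outcome variance.
    sd_d = delta.std()
    x_z = (delta - delta.mean()) / sd_d if sd_d > 0 else np.zeros(n)
    mediators = np.empty((n, config.n_regions))
    b_leak = np.zeros(n)
    for r, (a_str, b_str) in enumerate(config.region_paths):
        e_r = rng.normal(0.0, config.mediator_noise_sd, n)
        mediators[:, r] = a_str * x_z + e_r
        b_leak += b_str * e_r

    beta = np.where(delta > 0, params.beta_pos, params.beta_neg)
    t2_val = np.clip(t1_val + beta * delta + config.mediator_to_vas * b_leak
                     + rng.normal(0.0, config.t2_noise_sd, n), 0.0, 1.0)
    t2_raw = np.where(neg, 1.0 - t2_val, t2_val)

    df = pd.DataFrame({
        "subject_id": params.subject_id,
        "group": params.group,
        "trial_index": np.arange(1, n + 1),
        "cue_id": [f"cue{i:02d}" for i in range(1, n + 1)],
        "cue_wording": wording,
        "self_eval_t1": t1_raw,
        "feedback_raw": fb_raw,
        "self_eval_t1_val": t1_val,
        "feedback_val": fb_val,
        "delta_eval": delta,
        "v_feedback": fb_val,
        "self_esteem": esteem,
        "self_eval_t2": t2_val,
        "self_eval_t2_raw": t2_raw,
    })
    for r in range(config.n_regions):
        df[f"mediator_{r + 1}"] = mediators[:, r]
    return df


def _draw_subject_params(subject_id: str, group: str, spec: GroupParamSpec,
                         latent_corr: float, rng) -> SubjectParams:
    """Draw one subject's ground truth.

    A latent asymmetry factor ``u`` is shared between the influence betas
    and the updating alphas (loading +sqrt(rho) on the positive member of
    each pair and -sqrt(rho) on the negative one), so the two valence
    biases are intercorrelated within group -- as observed empirically --
    while each parameter keeps its configured marginal mean and SD.
    """
    u = rng.normal()
    lo, hi = np.sqrt(1.0 - latent_corr), np.sqrt(latent_corr)

    def draw(d: ParamDist, load: float = 0.0) -> float:
        if load == 0.0:
            z = rng.normal()
        else:
            z = lo * rng.normal() + load * hi * u
        return float(np.clip(d.mean + d.sd * z, 0.0, 1.0))

    return SubjectParams(
        subject_id=subject_id, group=group,
        beta_pos=draw(spec.beta_pos, +1), beta_neg=draw(spec.beta_neg, -1),
        prior=draw(spec.prior), alpha_pos=draw(spec.alpha_pos, +1),
        alpha_neg=draw(spec.alpha_neg, -1), trait_eval_mean=draw(spec.trait_eval),
    )


def generate_cohort(config: GeneratorConfig | None = None) -> Cohort:
    """Generate a full two-group cohort, deterministic given ``config.seed``.

    Each subject gets an independent RNG substream spawned from the master
    seed, so the cohort is reproducible under subject-level parallelism.
    """
    config = (config or GeneratorConfig()).validate()
    groups = [GROUP_SAD] * config.n_sad + [GROUP_HC] * config.n_hc
    children = np.random.SeedSequence(config.seed).spawn(len(groups))
    frames, truth = [], []
    for i, (group, child) in enumerate(zip(groups, children)):
        rng = np.random.default_rng(child)
        sid = f"{group.lower()}{i + 1:03d}"
        params = _draw_subject_params(sid, group, config.group_params[group],
                                      config.latent_bias_corr, rng)
        truth.append(params)
        frames.append(simulate_subject(params, config, rng))
    trials = pd.concat(frames, ignore_index=True)
    return Cohort(trials=trials, ground_truth=truth, config=config)


# ---------------------------------------------------------------------------
# serialization

def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write the tidy trial CSV plus ground-truth and config JSON sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "trials": out / "trials.csv",
        "ground_truth": out / "ground_truth.json",
        "config": out / "config.json",
    }
    cohort.trials.to_csv(paths["trials"], index=False)
    with open(paths["ground_truth"], "w") as fh:
        json.dump([dataclasses.asdict(p) for p in cohort.ground_truth], fh, indent=1)
    with open(paths["config"], "w") as fh:
        json.dump(_config_to_dict(cohort.config), fh, indent=1)
    return paths


def read_cohort(in_dir) -> Cohort:
    """Read back a cohort written by :func:`write_cohort` (lossless)."""
    src = Path(in_dir)
    trials = pd.read_csv(src / "trials.csv")
    with open(src / "ground_truth.json") as fh:
        truth = [SubjectParams(**rec) for rec in json.load(fh)]
    with open(src / "config.json") as fh:
        config = config_from_dict(json.load(fh))
    return Cohort(trials=trials, ground_truth=truth, config=config)


def _config_to_dict(config: GeneratorConfig) -> dict:
    d = dataclasses.asdict(config)
    d["region_paths"] = [list(p) for p in config.region_paths]
    return d


def config_from_dict(d: dict, validate: bool = True) -> GeneratorConfig:
    """Build a GeneratorConfig from a plain mapping (JSON/YAML).

    With ``validate=False`` the config is only coerced, so callers can
    collect all invariant violations themselves.
    """
    d = dict(d)
    if "region_paths" in d:
        d["region_paths"] = [tuple(p) for p in d["region_paths"]]
    if "group_params" in d:
        gp = {}
        for g, spec in d["group_params"].items():
            if isinstance(spec, GroupParamSpec):
                gp[g] = spec
            else:
                gp[g] = GroupParamSpec(**{
                    k: v if isinstance(v, ParamDist) else ParamDist(**v)
                    for k, v in spec.items()
                })
        d["group_params"] = gp
    unknown = set(d) - {f.name for f in dataclasses.fields(GeneratorConfig)}
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    cfg = GeneratorConfig(**d)
    return cfg.validate() if validate else cfg
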