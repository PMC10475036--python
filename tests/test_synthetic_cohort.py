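"""Generator contracts: determinism, valence recoding, balance, bounds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import zero_noise_config
from sociallearn.affective_updating import RWParams, predict_trajectory
from sociallearn.synthetic_cohort import (ConfigError, GeneratorConfig,
                                          SubjectParams, draw_feedback,
                                          generate_cohort, read_cohort,
                                          simulate_subject, write_cohort)

VAS_COLS = ["self_eval_t1", "feedback_raw", "self_eval_t1_val", "feedback_val",
            "v_feedback", "self_esteem", "self_eval_t2", "self_eval_t2_raw"]


def _subject(**kw) -> SubjectParams:
    base = dict(subject_id="s1", group="HC", beta_pos=0.4, beta_neg=0.3,
                prior=0.5, alpha_pos=0.3, alpha_neg=0.2, trait_eval_mean=0.5)
    base.update(kw)
    return SubjectParams(**base)


class TestGenerateCohort:
    def test_default_shape_and_cue_split(self, default_cohort):
        trials = default_cohort.trials
        assert trials["subject_id"].nunique() == 44
        per_subject = trials.groupby("subject_id")
        assert (per_subject.size() == 52).all()
        pos_cues = per_subject["cue_wording"].apply(lambda w: (w == "positive").sum())
        assert (pos_cues == 26).all()
        groups = trials.groupby("group")["subject_id"].nunique()
        assert groups["SAD"] == 21 and groups["HC"] == 23
        assert len(default_cohort.ground_truth) == 44

    def test_seeded_determinism(self, default_cohort):
        again = generate_cohort(GeneratorConfig(seed=1))
        pd.testing.assert_frame_equal(default_cohort.trials, again.trials)

    def test_different_seeds_differ(self, default_cohort):
        other = generate_cohort(GeneratorConfig(seed=2))
        assert not default_cohort.trials["delta_eval"].equals(other.trials["delta_eval"])

    def test_zero_mismatch_sd_gives_zero_delta(self):
        cohort = generate_cohort(GeneratorConfig(mismatch_sd=0.0, n_sad=2, n_hc=2, seed=3))
        assert (cohort.trials["delta_eval"] == 0.0).all()

    def test_mismatch_sign_balance_per_subject(self, default_cohort):
        for _, sub in default_cohort.trials.groupby("subject_id"):
            n_pos = (sub["delta_eval"] > 0).sum()
            assert abs(n_pos - 26) <= 2

    def test_mean_positive_fraction_over_seeds(self):
        fracs = []
        for seed in range(30):
            cohort = generate_cohort(GeneratorConfig(n_sad=2, n_hc=2, seed=seed))
            fracs.append((cohort.trials["delta_eval"] > 0).mean())
        assert 0.45 <= np.mean(fracs) <= 0.55

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigError, match="n_trials"):
            GeneratorConfig(n_trials=2).validate()
        with pytest.raises(ConfigError, match="mismatch_sd"):
            GeneratorConfig(mismatch_sd=-0.1).validate()


class TestValenceCoding:
    def test_negative_cues_recode_to_favorability(self, default_cohort):
        t = default_cohort.trials
        neg = t["cue_wording"] == "negative"
        assert np.allclose(t.loc[neg, "feedback_val"], 1 - t.loc[neg, "feedback_raw"])
        assert np.allclose(t.loc[neg, "self_eval_t1_val"], 1 - t.loc[neg, "self_eval_t1"])
        assert np.allclose(t.loc[~neg, "feedback_val"], t.loc[~neg, "feedback_raw"])
        assert np.allclose(t.loc[~neg, "self_eval_t1_val"], t.loc[~neg, "self_eval_t1"])

    def test_delta_definition(self, default_cohort):
        t = default_cohort.trials
        assert np.allclose(t["delta_eval"], t["feedback_val"] - t["self_eval_t1_val"])


class TestBoundedness:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        mismatch_sd=st.floats(0.01, 0.3),
        noise_sd=st.floats(0.0, 0.2),
        trait=st.floats(0.2, 0.8),
        seed=st.integers(0, 10_000),
    )
    def test_all_vas_fields_in_unit_interval(self, mismatch_sd, noise_sd, trait, seed):
        spec = GeneratorConfig().group_params
        cfg = GeneratorConfig(
            n_trials=12, n_sad=2, n_hc=2, mismatch_sd=mismatch_sd,
            rating_noise_sd=noise_sd, esteem_noise_sd=noise_sd,
            t2_noise_sd=noise_sd, seed=seed, group_params=spec,
        )
        trials = generate_cohort(cfg).trials
        for col in VAS_COLS:
            assert trials[col].between(0.0, 1.0).all(), col


class TestDrawFeedback:
    def test_zero_sd_returns_center(self, rng):
        fb, delta = draw_feedback(0.5, 0.0, rng)
        assert fb == 0.5 and delta == 0.0

    def test_clipping_at_upper_bound(self, rng):
        for _ in range(200):
            fb, delta = draw_feedback(1.0, 0.3, rng)
            assert fb <= 1.0 and delta <= 0.0

    def test_empirical_mismatch_sd(self, rng):
        deltas = [draw_feedback(0.5, 0.15, rng)[1] for _ in range(10_000)]
        assert 0.14 <= np.std(deltas) <= 0.16

    def test_rejects_out_of_range_rating(self, rng):
        with pytest.raises(ValueError):
            draw_feedback(1.2, 0.1, rng)


class TestSimulateSubjectDegenerate:
    def test_no_learning_keeps_esteem_at_prior(self, rng):
        cfg = zero_noise_config()
        df = simulate_subject(_subject(alpha_pos=0.0, alpha_neg=0.0, prior=0.5),
                              cfg, rng)
        assert np.allclose(df["self_esteem"], 0.5)

    def test_full_adoption_copies_feedback_to_t2(self, rng):
        cfg = zero_noise_config()
        df = simulate_subject(_subject(beta_pos=1.0, beta_neg=1.0), cfg, rng)
        assert np.allclose(df["self_eval_t2"], df["feedback_val"], atol=1e-12)

    def test_full_update_tracks_feedback_valence(self, rng):
        cfg = zero_noise_config()
        df = simulate_subject(_subject(alpha_pos=1.0, alpha_neg=1.0), cfg, rng)
        assert np.allclose(df["self_esteem"], df["v_feedback"], atol=1e-12)

    def test_esteem_follows_rw_recursion(self, rng):
        cfg = zero_noise_config()
        params = _subject(prior=0.3, alpha_pos=0.7, alpha_neg=0.2)
        df = simulate_subject(params, cfg, rng)
        expected = predict_trajectory(
            RWParams(prior=0.3, alpha_pos=0.7, alpha_neg=0.2),
            df["v_feedback"].to_numpy())
        assert np.allclose(df["self_esteem"], expected, atol=1e-12)


class TestSerialization:
    def test_row_count(self, tmp_path):
        cohort = generate_cohort(GeneratorConfig(n_trials=4, n_sad=2, n_hc=2, seed=7))
        paths = write_cohort(cohort, tmp_path)
        assert len(pd.read_csv(paths["trials"])) == 16

    def test_roundtrip_lossless(self, tmp_path):
        cohort = generate_cohort(GeneratorConfig(n_sad=2, n_hc=3, seed=11))
        write_cohort(cohort, tmp_path)
        back = read_cohort(tmp_path)
        num = cohort.trials.select_dtypes("number")
        assert np.allclose(num, back.trials[num.columns], atol=1e-12)
        assert back.ground_truth == cohort.ground_truth
        assert back.config == cohort.config

    def test_ground_truth_record_count(self, tmp_path, default_cohort):
        paths = write_cohort(default_cohort, tmp_path)
        import json

        with open(paths["ground_truth"]) as fh:
            assert len(json.load(fh)) == 44
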