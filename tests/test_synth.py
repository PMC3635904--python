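"""The synthetic-session generator: rule-consistent sequences, bell
profiles, bent trajectories, session structure and marginal laws."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import kinesig as ks
from conftest import sequence_features

LAW = ks.SpeedLaw(np.log(2.0), 0.1)


# ---------------------------------------------------------------------------
# generate_vmax_sequence
# ---------------------------------------------------------------------------

class TestVmaxSequence:

    @pytest.mark.parametrize("m, b", [(0.9, 0.3), (1.0, 0.0), (1.2, -0.4)])
    def test_noiseless_inversion_refits_exactly(self, m, b):
        rule = ks.RuleParams(m=m, b=b, eps_sd=0.0)
        v, a = ks.generate_vmax_sequence(LAW, rule, 100, 7)
        fit = ks.fit_rule(ks.build_rule_scatter(sequence_features(v, a)))
        assert fit.m == pytest.approx(m, abs=1e-9)
        assert fit.b == pytest.approx(b, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_same_seed_reproduces_bit_identical_sequences(self):
        rule = ks.RuleParams(m=0.9, b=0.3, eps_sd=0.05)
        v1, a1 = ks.generate_vmax_sequence(LAW, rule, 50, 123)
        v2, a2 = ks.generate_vmax_sequence(LAW, rule, 50, 123)
        assert np.array_equal(v1, v2) and np.array_equal(a1, a2)

    def test_residual_sd_matches_configuration(self):
        rule = ks.RuleParams(m=0.9, b=0.3, eps_sd=0.05,
                             direction="amax_first")
        v, a = ks.generate_vmax_sequence(LAW, rule, 500, 9, upsilon=2.0)
        scatter = ks.build_rule_scatter(sequence_features(v, a), upsilon=2.0)
        fit = ks.fit_rule(scatter)
        resid_sd = np.std(scatter.y - (fit.m * scatter.x + fit.b))
        assert resid_sd == pytest.approx(0.05, rel=0.2)

    def test_degenerate_parameters_are_rejected(self):
        with pytest.raises(ValueError):
            ks.RuleParams(m=0.0, b=0.0)
        with pytest.raises(ValueError):
            ks.generate_vmax_sequence(LAW, ks.RuleParams(1.0, 0.0), 1, 0)

    def test_marginal_peak_speeds_are_lognormal(self):
        v, _ = ks.generate_vmax_sequence(LAW, ks.RuleParams(1.0, 0.0),
                                         1000, 3)
        assert np.all(v > 0)
        assert stats.normaltest(np.log(v)).pvalue > 0.01


# ---------------------------------------------------------------------------
# generate_speed_profile
# ---------------------------------------------------------------------------

class TestSpeedProfile:

    def test_sampling_and_exact_peak(self):
        prof = ks.generate_speed_profile(3.0, 1.0, 240.0)
        assert len(prof) == 240
        assert prof.max() == pytest.approx(3.0, abs=1e-9)
        assert np.all(prof >= 0)
        assert prof[0] < 0.05 * prof.max() and prof[-1] < 0.05 * prof.max()

    def test_symmetric_profile_peaks_at_midpoint(self):
        fs = 240.0
        prof = ks.generate_speed_profile(2.0, 1.0, fs, peak_fraction=0.5)
        t_peak = np.argmax(prof) / fs
        assert t_peak == pytest.approx(0.5, abs=1.5 / fs)

    @pytest.mark.parametrize("pf", [0.2, 0.5, 0.8])
    def test_profile_is_strictly_unimodal(self, pf):
        prof = ks.generate_speed_profile(2.0, 1.2, 240.0, peak_fraction=pf)
        signs = np.sign(np.diff(prof))
        # exactly one maximal run transition +...+ to -...-
        changes = np.sum(np.diff(signs[signs != 0]) != 0)
        assert changes == 1

    @pytest.mark.parametrize("kwargs", [dict(vmax=-1, duration=1),
                                        dict(vmax=1, duration=0),
                                        dict(vmax=1, duration=1,
                                             peak_fraction=1.0)])
    def test_invalid_profiles_are_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ks.generate_speed_profile(sampling_rate=240.0, **kwargs)


# ---------------------------------------------------------------------------
# generate_trajectory
# ---------------------------------------------------------------------------

class TestTrajectory:

    def test_zero_bend_is_exactly_colinear(self):
        prof = ks.generate_speed_profile(2.0, 1.0, 240.0)
        pos = ks.generate_trajectory(prof, 240.0, [0, 0, 0], [0.6, 0, 0], 0.0)
        dev = ks.linearity_profile(pos, 50).deviations
        assert np.all(dev < 1e-9)

    def test_arc_length_integrates_the_speed_profile(self):
        prof = ks.generate_speed_profile(2.0, 1.0, 240.0)
        target = prof.sum() / 240.0
        for bend in (0.0, 0.3, 1.0):
            pos = ks.generate_trajectory(prof, 240.0, [0, 0, 0],
                                         [0.6, 0, 0], bend)
            length = np.sum(np.linalg.norm(np.diff(pos, axis=0), axis=1))
            assert length == pytest.approx(target, rel=0.01)

    def test_semicircular_template_deviation_equals_radius(self):
        # a profile traveling the arc length of a unit semicircle with
        # bend = 1 realizes that semicircle: max deviation = radius = 1
        fs = 240.0
        prof = ks.generate_speed_profile(2.0, 1.0, fs)
        prof = prof * (np.pi / (prof.sum() / fs))
        pos = ks.generate_trajectory(prof, fs, [-1, 0, 0], [1, 0, 0], 1.0)
        assert ks.linearity_profile(pos, 101).max_deviation == \
            pytest.approx(1.0, rel=0.01)

    def test_larger_bend_gives_larger_deviation(self):
        prof = ks.generate_speed_profile(2.0, 1.0, 240.0)
        devs = [ks.linearity_profile(
            ks.generate_trajectory(prof, 240.0, [0, 0, 0], [0.6, 0, 0], b),
            50).max_deviation for b in (0.1, 0.3, 0.6)]
        assert devs[0] < devs[1] < devs[2]

    def test_coincident_endpoints_are_rejected(self):
        prof = ks.generate_speed_profile(2.0, 1.0, 240.0)
        with pytest.raises(ValueError):
            ks.generate_trajectory(prof, 240.0, [1, 1, 1], [1, 1, 1], 0.0)


# ---------------------------------------------------------------------------
# generate_session
# ---------------------------------------------------------------------------

class TestSession:

    def test_trial_and_segment_counts(self, default_session):
        # 100 trials/condition x 2 speed levels x 1 context
        assert default_session.n_trials == 200
        assert default_session.n_segments == 400
        assert len(default_session.features) == 400

    def test_same_seed_gives_identical_sessions(self):
        cfg = ks.default_config(seed=5, trials_per_condition=10)
        s1, s2 = ks.generate_session(cfg), ks.generate_session(cfg)
        pd.testing.assert_frame_equal(s1.features, s2.features)
        assert all(np.array_equal(a.position, b.position)
                   for a, b in zip(s1.trials, s2.trials))

    def test_blocked_design_emits_contiguous_levels(self, default_session):
        strikes = default_session.features[
            default_session.features.segment == "strike"]
        levels = strikes.sort_values("trial_index").speed_level.to_numpy()
        assert np.sum(levels[:-1] != levels[1:]) == 1    # one block switch

    def test_random_design_interleaves_levels(self):
        cfg = ks.default_config(seed=6, design="random",
                                trials_per_condition=50)
        sess = ks.generate_session(cfg)
        strikes = sess.features[sess.features.segment == "strike"]
        levels = strikes.sort_values("trial_index").speed_level.to_numpy()
        assert np.sum(levels[:-1] != levels[1:]) > 10
        assert sorted(pd.unique(levels)) == ["fast", "slow"]

    def test_sessions_satisfy_the_rule_exactly_when_noiseless(self):
        subject = ks.SubjectProfile(
            "s1", "novice", ks.synth.default_speed_laws(("simulation",)),
            ks.RuleParams(m=0.9, b=0.3, eps_sd=0.0))
        cfg = ks.default_config(seed=8, trials_per_condition=20,
                                subject=subject)
        sess = ks.generate_session(cfg)
        for (segment, level), grp in sess.features.groupby(
                ["segment", "speed_level"]):
            fit = ks.fit_rule(ks.build_rule_scatter(
                grp.sort_values("trial_index")))
            assert fit.m == pytest.approx(0.9, abs=1e-9)
            assert fit.b == pytest.approx(0.3, abs=1e-9)

    def test_scaling_speeds_preserves_norm_vmax(self, default_session):
        feats = default_session.features
        k = 2.7
        scaled = feats.vmax * k / (feats.vmax * k + feats.mean_speed * k)
        assert np.allclose(scaled, feats.norm_vmax, rtol=1e-12)

    def test_expert_spans_wider_means_with_smaller_scales(self,
                                                          cohort_session):
        feats = cohort_session.features
        spreads, scales = {}, {}
        for sid, grp in feats[feats.segment == "strike"].groupby(
                "subject_id"):
            sigs = ks.condition_signatures(grp, "vmax")
            means = [s.mean for s in sigs.values()]
            spreads[sid] = max(means) / min(means)
            scales[sid] = max(s.scale for s in sigs.values())
        assert spreads["expert_1"] > spreads["novice_1"]
        assert scales["expert_1"] < scales["novice_1"]

    def test_extracted_features_close_the_loop(self):
        cfg = ks.default_config(seed=3, trials_per_condition=10)
        sess = ks.generate_session(cfg)
        ext = ks.features_table(sess, use_recorded=False)
        rec = sess.features
        assert np.allclose(ext.vmax, rec.vmax, rtol=1e-3)
        assert np.allclose(ext.amax, rec.amax, rtol=0.10)

    def test_invalid_configs_are_rejected(self):
        with pytest.raises(ValueError):
            ks.SynthConfig(subjects=())
        with pytest.raises(ValueError):
            ks.default_config(trials_per_condition=1)
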