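"""Synthetic-subject EMG generator, training protocol and closed loop."""

import numpy as np
import pytest

from myoarm.robot import ArmModel
from myoarm.subject import (PolicyParams, SubjectProfile,
                            attainable_elbow_extension,
                            build_training_protocol, generate_class_emg,
                            generate_unrelated_recordings, simulate_session,
                            user_policy)


class TestGenerateClassEmg:
    def test_same_seed_is_reproducible(self, profile):
        a = generate_class_emg(profile, "abduction", seed=5, duration_s=1.0)
        b = generate_class_emg(profile, "abduction", seed=5, duration_s=1.0)
        assert np.array_equal(a.samples, b.samples)

    def test_zero_intensity_leaves_only_sensor_noise(self, profile):
        rec = generate_class_emg(profile, "abduction", intensity=0.0,
                                 seed=3, duration_s=2.0)
        rms = np.sqrt(np.mean(rec.samples**2, axis=0))
        assert np.all(rms < 3.0 * profile.noise_sd)

    def test_mav_tracks_activation_pattern(self, profile):
        """Per-channel MAV of a long trial ≈ amplitude × √(2/π), i.e. it is
        proportional to the coupled activation pattern within 10%."""
        rec = generate_class_emg(profile, "abduction", seed=11, duration_s=10.0)
        mavs = np.mean(np.abs(rec.samples), axis=0)
        expect = profile.mvc_scale * profile.observed_activation(
            {"abduction": 1.0}, 45.0) * np.sqrt(2.0 / np.pi)
        strong = expect > 0.2  # noise dominates the quiet channels
        assert np.allclose(mavs[strong], expect[strong], rtol=0.10)

    def test_synergy_bleeds_into_flexors(self):
        """Abduction drive raises biceps/wrist-flexor amplitude when the
        synergy is on."""
        quiet = SubjectProfile(k_syn=0.0)
        coupled = SubjectProfile(k_syn=1.0)
        i_biceps = quiet.channel_names.index("biceps")
        a0 = quiet.observed_activation({"abduction": 1.0})[i_biceps]
        a1 = coupled.observed_activation({"abduction": 1.0})[i_biceps]
        assert a1 > a0

    def test_negative_intensity_rejected(self, profile):
        with pytest.raises(ValueError):
            generate_class_emg(profile, "abduction", intensity=-1.0)


class TestTrainingProtocol:
    def test_both_mode_emits_28_ten_second_trials(self, profile):
        trials = build_training_protocol(profile, "both", seed=0)
        assert len(trials) == 28
        assert all(t.duration_ms == 10_000.0 for t in trials)

    @pytest.mark.parametrize("mode", ["position", "force"])
    def test_single_mode_emits_23_with_11_no_movement(self, profile, mode):
        trials = build_training_protocol(profile, mode, seed=0,
                                         trial_duration_s=1.0)
        assert len(trials) == 23
        assert sum(t.label == "no_movement" for t in trials) == 11

    def test_three_postures_twice_per_class(self, profile):
        trials = build_training_protocol(profile, "both", seed=0,
                                         trial_duration_s=1.0)
        class_trials = [t for t in trials if not t.trial_id.startswith("train_reach")]
        assert len(class_trials) == 18
        postures = {t.posture for t in class_trials}
        assert postures == {0.0, 45.0, 90.0}

    def test_reach_trials_are_labeled_no_movement(self, profile):
        trials = build_training_protocol(profile, "both", seed=0,
                                         trial_duration_s=1.0)
        reach = [t for t in trials if t.trial_id.startswith("train_reach")]
        assert len(reach) == 10
        assert all(t.label == "no_movement" for t in reach)


class TestUserPolicy:
    def test_full_support_removes_lift_effort(self, profile):
        arm = ArmModel()
        out = user_policy("lift", None, arm.W, profile, arm=arm)
        assert out.intents["abduction"] == pytest.approx(PolicyParams().baseline)

    def test_no_support_demands_full_lift_effort(self, profile):
        arm = ArmModel()
        out = user_policy("lift", None, 0.0, profile, arm=arm)
        assert out.intents["abduction"] == pytest.approx(1.0)
        assert out.F_user_lift == pytest.approx(arm.W)

    def test_without_synergy_extension_ignores_effort(self):
        p = SubjectProfile(k_syn=0.0)
        lo = attainable_elbow_extension(p, 0.05)
        hi = attainable_elbow_extension(p, 1.0)
        assert lo == hi == pytest.approx(20.0)  # phi_rest − phi_range

    def test_synergy_makes_extension_effort_dependent(self, profile):
        """More shoulder effort → larger minimum flexion (less extension)."""
        efforts = [0.1, 0.4, 0.8]
        phis = [attainable_elbow_extension(profile, e) for e in efforts]
        assert phis[0] < phis[1] < phis[2]

    def test_unknown_phase_rejected(self, profile):
        with pytest.raises(ValueError):
            user_policy("fly", None, 0.0, profile)


class TestSimulateSession:
    def test_fixed_seed_is_bit_identical(self, profile):
        a = simulate_session(profile, "no_support", n_trials=1, seed=9)[0]
        b = simulate_session(profile, "no_support", n_trials=1, seed=9)[0]
        assert np.array_equal(a.emg, b.emg)
        assert np.array_equal(a.theta_abd, b.theta_abd)
        assert np.array_equal(a.F_sensed, b.F_sensed)

    def test_no_support_applies_zero_force(self, profile):
        trial = simulate_session(profile, "no_support", n_trials=1, seed=2)[0]
        assert np.all(trial.F_applied == 0.0)

    def test_limb_weight_applies_constant_weight(self, profile):
        trial = simulate_session(profile, "limb_weight", n_trials=1, seed=2)[0]
        assert np.all(trial.F_applied == ArmModel().W)

    def test_position_trial_reaches_window_and_presses_down(self, profile,
                                                            quick_model):
        """Closed-loop position control lifts the arm into the target window;
        while reaching, the user bears down on the rigid support (sustained
        negative sensed force)."""
        trial = simulate_session(profile, "position", n_trials=1, seed=2,
                                 model=quick_model)[0]
        assert not trial.truncated
        in_win = (trial.theta_abd >= 80.0) & (trial.theta_abd <= 100.0)
        assert in_win.any()
        assert trial.F_sensed[in_win].mean() < -0.5 * ArmModel().W

    def test_force_trial_reaches_window(self, profile, quick_model):
        trial = simulate_session(profile, "force", n_trials=1, seed=2,
                                 model=quick_model)[0]
        assert not trial.truncated
        assert np.max(trial.theta_abd) >= 80.0
        # support force stays within [0, W]
        assert trial.F_applied.min() >= 0.0
        assert trial.F_applied.max() <= ArmModel().W + 1e-9

    def test_decisions_made_every_25_ms(self, profile, quick_model):
        trial = simulate_session(profile, "position", n_trials=1, seed=2,
                                 model=quick_model, trial_duration_s=10.0)[0]
        assert len(trial.decisions) == 393
        times = [d.time_ms for d in trial.decisions]
        assert times[0] == 200.0 and np.all(np.diff(times) == 25.0)


class TestUnrelatedRecordings:
    def test_structure_and_durations(self, profile):
        recs = generate_unrelated_recordings(profile, "table", seed=1,
                                             n_trials=2, trial_duration_s=3.0)
        assert set(recs) == {"horizontal_add_abd", "internal_external_rot",
                             "elbow_flex_extend", "hand_open_close"}
        assert all(len(v) == 2 for v in recs.values())
        assert all(r.duration_ms == 3000.0 for v in recs.values() for r in v)

    def test_invalid_support_rejected(self, profile):
        with pytest.raises(ValueError):
            generate_unrelated_recordings(profile, "hover")
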