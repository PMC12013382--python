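"""Excursion metrics, EMG effort, paired tests and summary tables."""

import numpy as np
import pandas as pd
import pytest

from myoarm.evaluation import (condition_summary, confusion_average_row,
                               emg_effort, emg_envelope, excursion_metrics,
                               paired_one_sided_t, session_channel_max,
                               unrelated_movement_confusion)
from myoarm.robot import TrialRecord
from myoarm.subject import generate_class_emg


def _trial(theta_abd, theta_h, phi_e, emg=None, fs=1000.0):
    n = len(theta_abd)
    emg = np.zeros((n, 12)) if emg is None else emg
    z = np.zeros(n)
    return TrialRecord(
        time_ms=np.arange(n) * 1000.0 / fs, theta_abd=np.asarray(theta_abd, float),
        theta_h=np.asarray(theta_h, float), phi_e=np.asarray(phi_e, float),
        z=z, F_applied=z.copy(), F_sensed=z.copy(), emg=emg, fs=fs,
        condition="no_support", trial_id="t",
    )


class TestExcursionMetrics:
    def test_known_in_window_extremes(self):
        theta_abd = [70, 85, 90, 95, 75]
        phi_e = [90, 60, 40, 55, 20]      # min in-window is 40
        theta_h = [30, 50, 80, 70, 95]    # max in-window is 80
        r = excursion_metrics(_trial(theta_abd, theta_h, phi_e))
        assert r.valid
        assert r.elbow_deg == 40.0
        assert r.shoulder_deg == 80.0

    def test_never_entering_window_is_invalid(self):
        r = excursion_metrics(_trial([70, 75, 78], [30, 30, 30], [90, 90, 90]))
        assert not r.valid
        assert np.isnan(r.elbow_deg)

    def test_out_of_window_extreme_ignored(self):
        """A deeper elbow extension occurring below 80° abduction must not
        count toward the in-window metric."""
        theta_abd = [70, 85, 70]
        phi_e = [90, 50, 10]              # the 10° extreme is out of window
        r = excursion_metrics(_trial(theta_abd, [30, 60, 90], phi_e))
        assert r.elbow_deg == 50.0
        assert r.shoulder_deg == 60.0


class TestEmgEffort:
    def test_constant_signal_envelope_is_constant(self):
        emg = np.full((1000, 12), 0.5)
        env = emg_envelope(emg, 1000.0)
        assert np.allclose(env[300:], 0.5)

    def test_session_max_normalizes_to_one(self, rng):
        t = _trial(np.full(1000, 90.0), np.zeros(1000), np.zeros(1000),
                   emg=rng.standard_normal((1000, 12)))
        smax = session_channel_max([t])
        env = emg_envelope(t.emg, t.fs) / smax
        assert env.max(axis=0) == pytest.approx(np.ones(12))

    def test_amplitude_scale_invariance(self, rng):
        """Doubling every trial's amplitude leaves normalized sums unchanged."""
        emg = rng.standard_normal((2000, 12))
        t1 = _trial(np.full(2000, 90.0), np.zeros(2000), np.zeros(2000), emg=emg)
        t2 = _trial(np.full(2000, 90.0), np.zeros(2000), np.zeros(2000),
                    emg=2.0 * emg)
        e1 = emg_effort([t1], session_channel_max([t1]))
        e2 = emg_effort([t2], session_channel_max([t2]))
        assert e1 == pytest.approx(e2, rel=1e-12)

    def test_zero_max_channel_excluded_with_warning(self, rng):
        emg = rng.standard_normal((500, 12))
        emg[:, 0] = 0.0  # delt_ant silent
        t = _trial(np.full(500, 90.0), np.zeros(500), np.zeros(500), emg=emg)
        smax = session_channel_max([t])
        with pytest.warns(UserWarning, match="zero session"):
            val = emg_effort([t], smax)
        assert np.isfinite(val) and val > 0


class TestPairedT:
    def test_identical_vectors(self):
        with pytest.warns(UserWarning, match="zero variance"):
            t, p = paired_one_sided_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 0.5

    def test_published_elbow_comparison(self):
        """Paired one-sided t on the per-participant elbow excursions,
        real-time position support vs no support."""
        position = [27, 35, 45, 53, 48]
        no_support = [35, 49, 49, 72, 91]
        t, p = paired_one_sided_t(position, no_support, "less")
        assert t == pytest.approx(-2.571, abs=0.001)
        assert p == pytest.approx(0.031, abs=0.001)

    def test_against_closed_form_oracle(self, rng):
        """Agreement with the hand-rolled t formula on random paired data."""
        from scipy.stats import t as tdist
        for _ in range(100):
            n = int(rng.integers(3, 12))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            d = a - b
            t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(n))
            p_manual = tdist.cdf(t_manual, df=n - 1)
            t_got, p_got = paired_one_sided_t(a, b, "less")
            assert t_got == pytest.approx(t_manual, abs=1e-10)
            assert p_got == pytest.approx(p_manual, abs=1e-10)

    def test_zero_variance_degenerate(self):
        with pytest.warns(UserWarning, match="zero variance"):
            _, p = paired_one_sided_t([1.0, 2.0], [2.0, 3.0], "less")
        assert p == 0.0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_one_sided_t([1.0], [1.0, 2.0])


class TestConditionSummary:
    def test_published_no_support_group_row(self):
        """Group mean/SD across the five participant means."""
        vals = {"no_support": {f"p{i}": [v] for i, v in
                               enumerate([86, 63, 50, 49, 61])}}
        df = condition_summary(vals)
        assert df.loc["no_support", ("group", "mean")] == 61.8
        assert df.loc["no_support", ("group", "sd")] == 14.9

    def test_identical_trials_have_zero_sd(self):
        df = condition_summary({"c": {"p1": [5.0, 5.0, 5.0],
                                      "p2": [7.0, 7.0]}})
        assert df.loc["c", ("p1", "sd")] == 0.0

    def test_single_participant_group_sd_undefined(self):
        df = condition_summary({"c": {"p1": [5.0, 6.0]}})
        assert df.loc["c", ("group", "mean")] == 5.5
        assert np.isnan(df.loc["c", ("group", "sd")])

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="empty cell"):
            condition_summary({"c": {"p1": []}})


class TestConfusion:
    def test_average_row_is_unweighted_mean(self):
        assert confusion_average_row([[78, 6, 16], [70, 15, 15],
                                      [96, 3, 1], [84, 16, 1]])[0] == 82.0

    def test_published_rows_reproduce_published_averages(self):
        """Integer-rounded column means of the published per-task rows equal
        the published average rows for both support conditions."""
        limb_weight = [[78, 6, 16], [70, 15, 15], [96, 3, 1], [84, 16, 1]]
        tabletop = [[63, 13, 23], [74, 20, 6], [88, 7, 6], [75, 24, 0]]
        assert np.array_equal(np.round(confusion_average_row(limb_weight)),
                              [82, 10, 8])
        assert np.array_equal(np.round(confusion_average_row(tabletop)),
                              [75, 16, 9])

    def test_rows_sum_to_100(self, profile, quick_model):
        recs = {"elbow_flex_extend":
                [generate_class_emg(profile, "elbow_flex_extend",
                                    intensity=0.7, duration_s=2.0, seed=4)]}
        df = unrelated_movement_confusion(quick_model, recs, round_to=None)
        assert df.loc["elbow_flex_extend"].sum() == pytest.approx(100.0, abs=0.5)

    def test_trained_pattern_classifies_as_itself(self, profile, quick_model):
        """A clean no-movement recording is almost entirely assigned to the
        no-movement class."""
        recs = {"rest": [generate_class_emg(profile, "no_movement",
                                            duration_s=3.0, seed=6)]}
        df = unrelated_movement_confusion(quick_model, recs, round_to=None)
        assert df.loc["rest", "no_movement"] >= 95.0
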