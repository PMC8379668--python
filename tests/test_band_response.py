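"""Trial alignment, baseline referencing, averaging, windowed tests,
suppression index."""

import numpy as np
import pytest

import stimecog as se
from tests.conftest import simulate_cohort

THETA = se.DEFAULT_BANDS[1]


def make_trial(z_env, fs=10.0, window=(-20.0, 70.0), valid=None, band=THETA):
    """Build an AlignedTrial directly from a z-envelope array."""
    n = len(z_env)
    axis = window[0] + np.arange(n) / fs
    return se.AlignedTrial(
        recording_id="t",
        channel="HPC1-HPC2",
        band=band,
        time_axis_s=axis,
        z_envelope=np.asarray(z_env, dtype=float),
        valid_mask=np.ones(n, dtype=bool) if valid is None else valid,
    )


def noise_trials(rng, n_trials, fs=10.0, effect=0.0, window=(-20.0, 70.0)):
    """Trials of iid unit-variance noise, optionally with a step at onset."""
    n = int((window[1] - window[0]) * fs)
    axis = window[0] + np.arange(n) / fs
    out = []
    for _ in range(n_trials):
        env = rng.standard_normal(n)
        env[axis >= 0] += effect
        out.append(make_trial(env, fs=fs, window=window))
    return out


class TestAlignTrials:
    def test_baseline_segment_moments(self, theta_trials):
        for t in theta_trials[:5]:
            sel = (
                (t.time_axis_s >= -20)
                & (t.time_axis_s < -10)
                & t.valid_mask
            )
            assert abs(t.z_envelope[sel].mean()) < 1e-9
            assert t.z_envelope[sel].std() == pytest.approx(1.0, abs=1e-6)

    def test_baseline_referencing_idempotent(self, theta_trials):
        from stimecog.band_response import _reference_to_baseline

        t = theta_trials[0]
        again = _reference_to_baseline(
            t.z_envelope, t.time_axis_s, t.valid_mask, t.baseline_window_s
        )
        np.testing.assert_allclose(again, t.z_envelope, atol=1e-9)

    def test_only_middle_recordings_used(self, theta_cohort):
        recs, intervals, _ = theta_cohort
        trials = se.align_trials(recs, intervals, "HPC1-HPC2", THETA)
        # every simulated on-interval here is [30, 90) in 180 s -> all middle
        assert len(trials) == len(recs)
        # shift one recording's interval to the edge: it must be dropped
        modified = [
            se.StimInterval(iv.recording_id, 0.5, 60.0, "on", "simulated")
            if iv.recording_id == "r000"
            else iv
            for iv in intervals
        ]
        fewer = se.align_trials(recs, modified, "HPC1-HPC2", THETA)
        assert len(fewer) == len(recs) - 1

    def test_empty_set_error_reports_reason_counts(self, theta_cohort):
        recs, intervals, _ = theta_cohort
        edge = [
            se.StimInterval(iv.recording_id, 0.5, 60.0, "on", "simulated")
            for iv in intervals
        ]
        with pytest.raises(se.InsufficientDataError, match="position_begin"):
            se.align_trials(recs, edge, "HPC1-HPC2", THETA)

    def test_injected_theta_suppression_recovered(self, theta_trials):
        """Simulator-truth recovery: the injected -1.5 z effect decays with
        tau = 5 s, so the expected mean over (0, 5 s) is
        -1.5 * (tau/5)(1 - e^(-5/tau)) = -1.5 * 0.632."""
        axis, mean, sem, _ = se.trial_average(theta_trials)
        sel = (axis >= 0) & (axis < 5)
        got = mean[sel].mean()
        expected = -1.5 * (1 - np.exp(-1.0))
        tol = 3 * np.nanmean(sem[sel]) + 0.05 * abs(expected)
        assert got == pytest.approx(expected, abs=tol)


class TestTrialAverage:
    def test_identical_trials_sem_zero(self):
        env = np.sin(np.linspace(0, 10, 900))
        trials = [make_trial(env.copy()) for _ in range(5)]
        _, mean, sem, _ = se.trial_average(trials)
        np.testing.assert_allclose(sem, 0, atol=1e-12)
        np.testing.assert_allclose(mean, env, atol=1e-12)

    def test_sem_matches_closed_form_for_iid_noise(self):
        rng = np.random.default_rng(3)
        n_trials = 40
        trials = noise_trials(rng, n_trials)
        _, _, sem, _ = se.trial_average(trials)
        assert np.nanmean(sem) == pytest.approx(1 / np.sqrt(n_trials), rel=0.05)

    def test_fewer_than_two_trials_raises(self):
        with pytest.raises(se.InsufficientDataError):
            se.trial_average([make_trial(np.zeros(900))])

    def test_sustained_delta_vs_phasic_theta_pattern(self):
        """Fully sustained delta suppression stays depressed late in the
        on-interval while a purely phasic theta effect returns toward 0."""
        effects = (
            se.BandEffect(se.BandDef("delta", 1, 5), "HPC", -1.2,
                          decay_tau_s=5.0, sustained_fraction=1.0),
            se.BandEffect(se.BandDef("theta", 5, 10), "HPC", -1.2,
                          decay_tau_s=5.0, sustained_fraction=0.0),
        )
        recs, intervals, _ = simulate_cohort(
            12, seed=21, band_effects=effects
        )
        late = {}
        for band in (se.DEFAULT_BANDS[0], se.DEFAULT_BANDS[1]):
            trials = se.align_trials(recs, intervals, "HPC1-HPC2", band)
            axis, mean, _, _ = se.trial_average(trials)
            late[band.name] = mean[(axis >= 50) & (axis < 60)].mean()
        assert late["delta"] < -0.5
        assert late["theta"] > late["delta"] + 0.4


class TestWindowedPairedTest:
    def test_adjusted_alpha_for_14_windows(self):
        rng = np.random.default_rng(4)
        res = se.windowed_paired_test(noise_trials(rng, 10))
        assert len(res) == 14
        assert res[0].alpha_adjusted == pytest.approx(0.0036, abs=5e-5)
        assert res[0].n_tests == 14

    def test_identical_window_and_baseline_gives_null_result(self):
        env = np.ones(900)
        trials = [make_trial(env * k) for k in (1.0, 2.0, 3.0)]
        res = se.windowed_paired_test(trials)
        assert all(r.t_statistic == 0.0 and r.p_value == 1.0 for r in res)
        assert not any(r.significant for r in res)

    def test_too_few_trials_raises(self):
        rng = np.random.default_rng(5)
        with pytest.raises(se.InsufficientDataError):
            se.windowed_paired_test(noise_trials(rng, 2))

    def test_power_against_injected_step_effect(self):
        """A -2 z step at onset with 40 trials is detected in the first
        post-onset window in (almost) every seeded run."""
        hits = 0
        n_runs = 30
        for k in range(n_runs):
            rng = np.random.default_rng(1000 + k)
            res = se.windowed_paired_test(noise_trials(rng, 40, effect=-2.0))
            hits += res[0].significant
        assert hits >= int(0.95 * n_runs)

    def test_size_under_null(self):
        """Without an effect, the first window is significant at the
        Bonferroni level only rarely."""
        hits = 0
        n_runs = 100
        for k in range(n_runs):
            rng = np.random.default_rng(5000 + k)
            res = se.windowed_paired_test(noise_trials(rng, 20))
            hits += res[0].significant
        assert hits <= 3


class TestSuppressionIndex:
    fs = 250.0

    def _recording_with_step(self, amp_pre, amp_post, onset=90.0, dur=180.0):
        t = np.arange(int(dur * self.fs)) / self.fs
        amp = np.where(t < onset, amp_pre, amp_post)
        sig = amp * np.sin(2 * np.pi * 7 * t)
        return se.Recording(np.tile(sig, (4, 1)), self.fs)

    def test_flat_envelope_gives_zero(self):
        rec = self._recording_with_step(1.0, 1.0)
        iv = se.StimInterval("r", 90.0, 150.0, "on")
        si = se.suppression_index(rec, iv, THETA)
        assert si.value_z == pytest.approx(0.0, abs=0.02)

    def test_negative_step_gives_positive_index(self):
        rec = self._recording_with_step(2.0, 1.0)
        iv = se.StimInterval("r", 90.0, 150.0, "on")
        si = se.suppression_index(rec, iv, THETA)
        assert si.value_z == pytest.approx(1.0, abs=0.1)

    def test_simulator_truth_with_slow_decay(self):
        """effect_z = -1 with tau >> 5 s: the index approximates one
        baseline-envelope SD, measured on the off period as the oracle."""
        effects = (se.BandEffect(THETA, "HPC", -1.0, decay_tau_s=500.0),)
        cfg = se.SimConfig(duration_s=180.0, seed=33, band_effects=effects)
        rec, truth = se.simulate_recording(cfg)
        pre = se.standard_preprocess(rec)
        iv = truth.on_intervals[0]
        si = se.suppression_index(pre, iv, THETA, channel="HPC1-HPC2")
        # oracle: envelope SD over stimulation-off samples
        bs = se.band_signal(pre, THETA)
        off = bs.valid_mask.copy()
        off[int(iv.start_s * self.fs) : int((iv.end_s + 10) * self.fs)] = False
        env_sd = bs.envelope[0, off].std()
        assert si.value_z == pytest.approx(env_sd, rel=0.45)

    def test_insufficient_coverage_raises(self):
        rec = self._recording_with_step(1.0, 1.0)
        rec.valid_mask[int(86 * self.fs) : int(94 * self.fs)] = False
        iv = se.StimInterval("r", 90.0, 150.0, "on")
        with pytest.raises(se.InsufficientDataError):
            se.suppression_index(rec, iv, THETA)
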