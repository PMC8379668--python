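"""Alias arithmetic, artifact envelope, interval detection, controls."""

import numpy as np
import pytest

import stimecog as se
from tests.conftest import simulate_cohort


class TestAliasFrequency:
    @pytest.mark.parametrize(
        "stim,fs,expected",
        [
            (145.0, 250.0, 105.0),
            (80.0, 250.0, 80.0),
            (125.0, 250.0, 125.0),
            (300.0, 250.0, 50.0),
        ],
    )
    def test_known_folds(self, stim, fs, expected):
        assert se.alias_frequency(stim, fs) == pytest.approx(expected)

    def test_nonpositive_inputs_raise(self):
        with pytest.raises(se.ConfigError):
            se.alias_frequency(0.0, 250.0)
        with pytest.raises(se.ConfigError):
            se.alias_frequency(145.0, -1.0)

    def test_fold_matches_arithmetic_oracle_bulk(self):
        """10,000 random pairs against the brute-force minimum-distance fold."""
        rng = np.random.default_rng(0)
        f = rng.uniform(0.5, 2000, 10_000)
        fs = rng.uniform(50, 1000, 10_000)
        got = np.array([se.alias_frequency(a, b) for a, b in zip(f, fs)])
        ks = np.arange(0, 50)
        brute = np.array(
            [np.min(np.abs(a - ks * b)) for a, b in zip(f, fs)]
        )
        np.testing.assert_allclose(got, brute, atol=1e-9)
        assert np.all(got <= fs / 2 + 1e-9)

    def test_fold_matches_fft_peak_of_sampled_sinusoid(self):
        """The folded frequency is where an actually-sampled sinusoid lands."""
        rng = np.random.default_rng(1)
        n = 4096
        for _ in range(100):
            fs = rng.uniform(100, 500)
            f = rng.uniform(5, 3 * fs)
            # skip near-bin-edge folds where leakage can move the argmax
            alias = se.alias_frequency(f, fs)
            if alias < 2 * fs / n or alias > fs / 2 - 2 * fs / n:
                continue
            t = np.arange(n) / fs
            spec = np.abs(np.fft.rfft(np.sin(2 * np.pi * f * t) * np.hanning(n)))
            peak = np.fft.rfftfreq(n, 1 / fs)[np.argmax(spec)]
            assert abs(peak - alias) <= fs / n


class TestArtifactEnvelope:
    def test_on_epochs_elevated_off_depressed(self, streamed_recording):
        rec, truth = streamed_recording
        z = se.artifact_envelope(rec, 105.0)
        on = np.zeros(rec.n_samples, dtype=bool)
        fs = rec.sampling_rate_hz
        for iv in truth.on_intervals:
            on[int(iv.start_s * fs) : int(iv.end_s * fs)] = True
        assert z[on].mean() > 0 > z[~on].mean()

    def test_band_outside_nyquist_raises(self, demo_recording):
        rec, _ = demo_recording
        with pytest.raises(se.ConfigError):
            se.artifact_envelope(rec, 125.0)

    def test_no_artifact_gives_no_long_threshold_runs(self):
        """Monte-Carlo false-positive check: artifact-free recordings produce
        no supra-zero alias-envelope run of 10 s or more."""
        false_pos = 0
        rng = np.random.default_rng(42)
        for _ in range(50):
            cfg = se.SimConfig(
                duration_s=120.0,
                artifact_amplitude=0.0,
                discharge_rate_off_per_min=0.0,
                discharge_rate_on_per_min=0.0,
                seed=int(rng.integers(2**31)),
            )
            rec, _ = se.simulate_recording(cfg)
            z = se.artifact_envelope(rec, 105.0)
            ivs = se.detect_on_intervals(z, rec.sampling_rate_hz)
            false_pos += len(ivs)
        assert false_pos == 0

    def test_always_on_recording_flagged_by_qc(self):
        cfg = se.SimConfig(
            duration_s=120.0, duty_on_s=600.0, duty_off_s=1.0, duty_phase_s=-10.0,
            seed=5,
        )
        rec, _ = se.simulate_recording(cfg)
        with pytest.warns(UserWarning, match="always_on|ambiguous"):
            _, qc = se.segment_recording(rec)
        assert qc.status != "ok"


class TestDetectOnIntervals:
    fs = 250.0

    def _z_from_runs(self, runs, total_s=200.0, level=3.0):
        z = -np.ones(int(total_s * self.fs))
        for s, e in runs:
            z[int(s * self.fs) : int(e * self.fs)] = level
        return z

    def test_detects_runs_and_merges_short_gaps(self):
        z = self._z_from_runs([(30.0, 60.0), (61.0, 90.0)])  # 1 s gap
        ivs = se.detect_on_intervals(z, self.fs)
        assert len(ivs) == 1
        assert ivs[0].start_s == pytest.approx(30.0, abs=0.01)
        assert ivs[0].end_s == pytest.approx(90.0, abs=0.01)

    def test_all_negative_envelope_gives_empty_list(self):
        assert se.detect_on_intervals(self._z_from_runs([]), self.fs) == []

    def test_run_below_min_duration_excluded(self):
        z = self._z_from_runs([(30.0, 38.0)])  # 8 s < 10 s
        assert se.detect_on_intervals(z, self.fs) == []

    def test_long_gaps_not_merged(self):
        z = self._z_from_runs([(10.0, 25.0), (40.0, 55.0)])
        assert len(se.detect_on_intervals(z, self.fs)) == 2


class TestClassifyPosition:
    def _iv(self, s, e):
        return se.StimInterval("r0", s, e)

    def test_middle(self):
        assert se.classify_position([self._iv(70, 130)], 180.0).label == "middle"

    def test_begin(self):
        assert se.classify_position([self._iv(0.0001, 60)], 180.0).label == "begin"

    def test_insufficient_baseline_is_begin(self):
        assert se.classify_position([self._iv(10, 70)], 180.0).label == "begin"

    def test_end(self):
        assert se.classify_position([self._iv(120, 180)], 180.0).label == "end"

    def test_multiple_and_none(self):
        ivs = [self._iv(10, 70), self._iv(310, 370)]
        assert se.classify_position(ivs, 900.0).label == "multiple"
        assert se.classify_position([], 180.0).label == "none"


class TestMatchControlInterval:
    def _setup(self, seed=0):
        rec, truth = se.simulate_recording(se.SimConfig(duration_s=180.0, seed=9))
        on = truth.on_intervals[0]
        on = se.StimInterval("r0", on.start_s, on.end_s, "on", "alias_detected")
        return rec, on

    def test_control_matches_duration_and_avoids_on_plus_guard(self):
        rec, on = self._setup()
        ctrl = se.match_control_interval(on, rec, [on], seed=3)
        assert ctrl.duration_s == pytest.approx(on.duration_s)
        assert ctrl.state == "off_control"
        # zero overlap with the on-interval extended by the guard
        assert ctrl.end_s <= on.start_s or ctrl.start_s >= on.end_s + 10.0

    def test_identical_seed_identical_placement(self):
        rec, on = self._setup()
        a = se.match_control_interval(on, rec, [on], seed=7)
        b = se.match_control_interval(on, rec, [on], seed=7)
        assert a == b

    def test_unique_feasible_placement_returned(self):
        """Off-region exactly equal to the on duration: enumeration of
        feasible starts leaves exactly one."""
        rec, _ = self._setup()
        # detected on-interval [30, 90) + 10 s guard leaves [0, 30) and
        # [100, 180) free; an 80 s control fits only at exactly [100, 180)
        detected = se.StimInterval("r0", 30.0, 90.0, "on")
        want_80s = se.StimInterval("r0", 100.0, 180.0, "on")
        ctrl = se.match_control_interval(want_80s, rec, [detected], seed=1)
        assert ctrl.start_s == pytest.approx(100.0)
        assert ctrl.end_s == pytest.approx(180.0)

    def test_no_feasible_placement_raises(self):
        rec, on = self._setup()
        long_on = se.StimInterval("r0", 10.0, 170.0, "on")
        with pytest.raises(se.InsufficientDataError):
            se.match_control_interval(long_on, rec, [long_on], seed=0)


class TestSegmentationRecovery:
    def test_boundary_error_and_sensitivity_over_cohort(self):
        """Over 50 seeded simulations at default artifact amplitude, every
        >= 30 s truth interval is detected and boundary errors stay small."""
        rng = np.random.default_rng(99)
        errors = []
        detected_all = True
        for _ in range(50):
            cfg = se.SimConfig(
                duration_s=180.0,
                duty_phase_s=float(rng.uniform(0, 360)),
                seed=int(rng.integers(2**31)),
            )
            rec, truth = se.simulate_recording(cfg)
            ivs, _ = se.segment_recording(rec)
            for tiv in truth.on_intervals:
                if tiv.duration_s < 30:
                    continue
                hits = [
                    iv
                    for iv in ivs
                    if min(iv.end_s, tiv.end_s) - max(iv.start_s, tiv.start_s)
                    > 0.5 * tiv.duration_s
                ]
                if not hits:
                    detected_all = False
                    continue
                errors.append(abs(hits[0].start_s - tiv.start_s))
                errors.append(abs(hits[0].end_s - tiv.end_s))
        assert detected_all
        errors = np.array(errors)
        # interior boundaries recovered to within 2 s (edge-clipped intervals
        # can only err inward and are included here too)
        assert np.quantile(errors, 0.95) <= 2.0
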