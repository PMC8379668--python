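"""Generator contracts: determinism, duty arithmetic, spectral properties,
discharge statistics, blanking conservation, longitudinal trends."""

import numpy as np
import pytest
from scipy import signal as sps

import stimecog as se


class TestConfigValidation:
    def test_nonpositive_duration_or_rate_rejected(self):
        with pytest.raises(se.ConfigError):
            se.SimConfig(duration_s=0.0)
        with pytest.raises(se.ConfigError):
            se.SimConfig(sampling_rate_hz=-250.0)
        with pytest.raises(se.ConfigError):
            se.SimConfig(discharge_rate_on_per_min=-1.0)

    def test_blanking_width_must_fit_cadence(self):
        with pytest.raises(se.ConfigError):
            se.SimConfig(blanking_interval_s=0.01, blanking_width_ms=40.0)

    def test_short_recording_warns(self):
        with pytest.warns(UserWarning, match="duty cycle"):
            se.simulate_recording(se.SimConfig(duration_s=120.0, seed=0))


class TestDeterminism:
    def test_identical_seed_bit_identical_output(self):
        cfg = dict(duration_s=180.0, seed=77)
        rec_a, truth_a = se.simulate_recording(se.SimConfig(**cfg))
        rec_b, truth_b = se.simulate_recording(se.SimConfig(**cfg))
        np.testing.assert_array_equal(rec_a.signal, rec_b.signal)
        np.testing.assert_array_equal(
            truth_a.discharge_times_s, truth_b.discharge_times_s
        )
        np.testing.assert_array_equal(truth_a.blanking_mask, truth_b.blanking_mask)

    def test_different_seed_different_signal(self):
        rec_a, _ = se.simulate_recording(se.SimConfig(duration_s=180.0, seed=1))
        rec_b, _ = se.simulate_recording(se.SimConfig(duration_s=180.0, seed=2))
        assert not np.array_equal(rec_a.signal, rec_b.signal)


class TestDutyCycle:
    def test_single_middle_interval_in_180s(self):
        ivs = se.duty_cycle_intervals(180.0, 60.0, 300.0, phase_s=60.0)
        assert len(ivs) == 1
        assert (ivs[0].start_s, ivs[0].end_s) == (60.0, 120.0)

    def test_ground_truth_matches_duty_arithmetic(self, streamed_recording):
        _, truth = streamed_recording
        starts = [iv.start_s for iv in truth.on_intervals]
        assert starts == [30.0, 390.0, 750.0]
        assert all(iv.duration_s == 60.0 for iv in truth.on_intervals)
        # non-overlapping and sorted
        for a, b in zip(truth.on_intervals[:-1], truth.on_intervals[1:]):
            assert a.end_s <= b.start_s

    def test_clipped_interval_at_recording_start(self):
        ivs = se.duty_cycle_intervals(180.0, 60.0, 300.0, phase_s=-30.0)
        assert ivs[0].start_s == 0.0
        assert ivs[0].end_s == 30.0


class TestSpectralProperties:
    def _band_power(self, rec, mask, lo, hi):
        f, p = sps.periodogram(rec.signal[0][mask], fs=rec.sampling_rate_hz)
        sel = (f >= lo) & (f <= hi)
        return p[sel].mean()

    def test_alias_band_power_higher_during_on(self, streamed_recording):
        """Periodogram oracle on the generator's own output."""
        rec, truth = streamed_recording
        fs = rec.sampling_rate_hz
        on = np.zeros(rec.n_samples, dtype=bool)
        for iv in truth.on_intervals:
            on[int(iv.start_s * fs) : int(iv.end_s * fs)] = True
        assert self._band_power(rec, on, 103, 107) > 10 * self._band_power(
            rec, ~on, 103, 107
        )

    def test_no_artifact_no_alias_contrast(self):
        cfg = se.SimConfig(duration_s=900.0, artifact_amplitude=0.0, seed=31)
        rec, truth = se.simulate_recording(cfg)
        fs = rec.sampling_rate_hz
        on = np.zeros(rec.n_samples, dtype=bool)
        for iv in truth.on_intervals:
            on[int(iv.start_s * fs) : int(iv.end_s * fs)] = True
        ratio = self._band_power(rec, on, 103, 107) / self._band_power(
            rec, ~on, 103, 107
        )
        assert 0.5 < ratio < 2.0

    @pytest.mark.parametrize("mode", ["alias", "pulse_train"])
    def test_largest_high_frequency_peak_at_alias(self, mode):
        """With the artifact on, the dominant component above 90 Hz sits at
        alias_frequency(stim, fs) within one frequency bin — in both the
        direct alias injection and the physical pulse-train mode."""
        cfg = se.SimConfig(duration_s=180.0, duty_phase_s=-1000.0,
                           duty_on_s=1e6, seed=13)  # always on
        rec, _ = se.simulate_recording(cfg, mode=mode)
        f, p = sps.welch(rec.signal[0], fs=250.0, nperseg=4096)
        sel = f > 90
        peak = f[sel][np.argmax(p[sel])]
        assert abs(peak - 105.0) <= 250.0 / 4096


class TestDischarges:
    def test_zero_rates_give_empty_list(self):
        out = se.generate_discharges(0.0, 0.0, [], 600.0, seed=0)
        assert len(out) == 0

    def test_poisson_count_within_three_sigma(self):
        out = se.generate_discharges(60.0, 0.0, [], 600.0, seed=1)
        assert abs(len(out) - 600) < 3 * np.sqrt(600)
        assert np.all(np.diff(out) >= 0)
        assert out.min() >= 0 and out.max() < 600.0

    def test_zero_on_rate_keeps_on_intervals_empty(self):
        ivs = [se.StimInterval("r", 100.0, 200.0, "truth_on", "simulated")]
        out = se.generate_discharges(10.0, 0.0, ivs, 600.0, seed=2)
        assert len(out) > 0
        assert not np.any((out >= 100.0) & (out < 200.0))

    def test_negative_rate_raises(self):
        with pytest.raises(se.ConfigError):
            se.generate_discharges(-1.0, 0.0, [], 60.0, seed=0)


class TestBlanking:
    def test_mask_marks_exactly_injected_samples(self, demo_recording):
        rec, truth = demo_recording
        fs = rec.sampling_rate_hz
        width = int(round(0.040 * fs))
        expected = np.zeros(rec.n_samples, dtype=bool)
        t = 13.0
        while t < rec.duration_s:
            i0 = int(round(t * fs))
            expected[i0 : min(rec.n_samples, i0 + width)] = True
            t += 47.0
        np.testing.assert_array_equal(truth.blanking_mask, expected)
        # the signal really is constant there
        i0 = int(round(13.0 * fs))
        assert np.ptp(rec.signal[:, i0 - 1 : i0 + width], axis=1).max() == 0

    def test_detector_recovers_injected_blanks(self, demo_recording):
        rec, truth = demo_recording
        detected = se.detect_blanking(rec)
        # every injected blank is covered by the detection (guard widens it)
        assert detected[truth.blanking_mask].all()
        # detection adds at most the guard margin around each blank
        guard = int(round(0.008 * rec.sampling_rate_hz)) + 1
        allowed = np.convolve(
            truth.blanking_mask.astype(int), np.ones(2 * guard + 1), mode="same"
        ).astype(bool)
        assert not detected[~allowed].any()


class TestLongitudinal:
    def _schedule(self, **kw):
        base = dict(
            voltage_epochs=((0, 90, 2.0), (90, 180, 3.0)),
            recordings_per_day=1,
        )
        base.update(kw)
        return se.LongitudinalSchedule(**base)

    def test_overlapping_epochs_rejected(self):
        with pytest.raises(se.ConfigError):
            se.LongitudinalSchedule(voltage_epochs=((0, 100, 2.0), (50, 150, 3.0)))

    def test_catalog_row_count(self):
        sched = se.LongitudinalSchedule(
            voltage_epochs=((0, 30, 2.0),), recordings_per_day=4
        )
        catalog, summaries, _ = se.simulate_longitudinal(sched, se.SimConfig(seed=0))
        assert len(catalog) == 120
        assert len(summaries) == 120

    def test_zero_trend_zero_noise_gives_exactly_flat_series(self):
        sched = self._schedule(
            suppression_trend_z_per_day=0.0,
            suppression_noise_sd=0.0,
        )
        _, summaries, _ = se.simulate_longitudinal(sched, se.SimConfig(seed=1))
        tr = se.ols_trend(
            summaries["days_since_implant"], summaries["theta_suppression_z"]
        )
        assert tr.slope_per_day == pytest.approx(0.0, abs=1e-15)

    def test_seeded_slope_recovery_within_20_percent(self):
        sched = self._schedule(
            suppression_trend_z_per_day=0.0033,
            suppression_noise_sd=0.05,
            recordings_per_day=2,
        )
        _, summaries, _ = se.simulate_longitudinal(sched, se.SimConfig(seed=2))
        tr = se.ols_trend(
            summaries["days_since_implant"], summaries["theta_suppression_z"]
        )
        assert tr.slope_per_day == pytest.approx(0.0033, rel=0.20)

    def test_voltage_lookup_and_epoch_bounds(self):
        sched = self._schedule()
        assert sched.voltage_on_day(0) == 2.0
        assert sched.voltage_on_day(89.9) == 2.0
        assert sched.voltage_on_day(90) == 3.0
        with pytest.raises(se.ConfigError):
            sched.voltage_on_day(500)


def test_write_dataset_produces_consistent_files(tmp_path):
    manifest = se.write_dataset(tmp_path, n_recordings=3, seed=4,
                                file_format="csv")
    entries = se.read_catalog(tmp_path / "catalog.csv")
    assert len(entries) == 3
    se.io.check_catalog_integrity(entries, tmp_path)
    rec = se.read_recording(tmp_path / entries[0].path)
    assert rec.n_channels == 4
    assert rec.sampling_rate_hz == 250.0
    events = se.read_events(tmp_path / "events.csv")
    assert set(events["recording_id"]).issubset({e.recording_id for e in entries})
    assert manifest["n_recordings"] == 3
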