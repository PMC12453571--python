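import numpy as np
import pytest

from stsbalance import (
    InertialRecording,
    StsFailure,
    StsParams,
    StsSimConfig,
    TooFewRepsError,
    UsageError,
    analyze_sts,
    detect_sts_repetitions,
    preprocess_gyro,
    simulate_slb,
    simulate_sts,
    time_to_reps,
)
from stsbalance.synthetic_imu import SlbSimConfig


def _filtered_sinusoid_gain(freq_hz, sts_meta):
    fs = 100.0
    t = np.arange(0, 40, 1 / fs)
    sig = np.sin(2 * np.pi * freq_hz * t)
    rec = InertialRecording(
        t=t, accel=np.zeros((len(t), 3)), gyro=np.tile(sig[:, None], 3),
        meta=sts_meta,
    )
    y, _ = preprocess_gyro(rec)
    core = y[len(y) // 4: 3 * len(y) // 4]
    return float(np.max(np.abs(core)))


class TestPreprocess:
    def test_constant_offset_removed(self, sts_meta):
        n = 2000
        rec = InertialRecording(
            t=np.arange(n) / 100.0, accel=np.zeros((n, 3)),
            gyro=np.full((n, 3), 0.7), meta=sts_meta,
        )
        y, _ = preprocess_gyro(rec)
        assert np.max(np.abs(y)) < 1e-9

    def test_passband_sinusoid_preserved(self, sts_meta):
        assert _filtered_sinusoid_gain(1.0, sts_meta) == pytest.approx(1.0, abs=0.02)

    def test_stopband_sinusoid_attenuated(self, sts_meta):
        assert _filtered_sinusoid_gain(20.0, sts_meta) < 0.10

    def test_too_short_recording_rejected(self, small_recording):
        with pytest.raises(ValueError):
            preprocess_gyro(small_recording)


class TestDetection:
    def test_noise_free_peaks_at_true_times(self, clean_sts):
        rec, truth = clean_sts
        y, fs = preprocess_gyro(rec)
        events = detect_sts_repetitions(y, fs)
        assert len(events) == 5
        for ev, (t_stand, t_sit) in zip(events, truth.rep_event_times):
            assert ev.stand_peak_s == pytest.approx(t_stand, abs=0.1)
            assert ev.sit_peak_s == pytest.approx(t_sit, abs=0.1)

    def test_peak_times_match_brute_force_argmax(self, clean_sts):
        # oracle: exhaustive scan for the sample-level extremum of each pulse
        rec, truth = clean_sts
        y, fs = preprocess_gyro(rec)
        events = detect_sts_repetitions(y, fs)
        for ev, (t_stand, t_sit) in zip(events, truth.rep_event_times):
            for det, tc, sign in ((ev.stand_peak_s, t_stand, +1), (ev.sit_peak_s, t_sit, -1)):
                lo, hi = int((tc - 1.0) * fs), int((tc + 1.0) * fs)
                oracle = (lo + np.argmax(sign * y[lo:hi])) / fs
                assert abs(det - oracle) <= 1.0 / fs

    def test_all_zero_signal_yields_no_events(self):
        assert detect_sts_repetitions(np.zeros(5000), 100.0) == []

    def test_amplitude_scale_invariance(self):
        rec, _ = simulate_sts(StsSimConfig(seed=21))
        y, fs = preprocess_gyro(rec)
        base = detect_sts_repetitions(y, fs)
        assert base
        for k in (0.01, 3.0, 1e4):
            scaled = detect_sts_repetitions(k * y, fs)
            assert [(e.stand_peak_s, e.sit_peak_s) for e in scaled] == [
                (e.stand_peak_s, e.sit_peak_s) for e in base
            ]

    def test_snr5_monte_carlo_detection(self):
        # 5 events recovered in >= 95 of 100 seeded runs at SNR 5
        hits = 0
        for s in range(100):
            rec, _ = simulate_sts(StsSimConfig(seed=s, noise_gyro_sd=0.3))
            y, fs = preprocess_gyro(rec)
            if len(detect_sts_repetitions(y, fs)) == 5:
                hits += 1
        assert hits >= 95

    def test_noise_monotonicity_in_expectation(self):
        # increasing noise never increases the expected number of runs
        # recovering the true rep count
        def hit_rate(noise_sd):
            hits = 0
            for s in range(40):
                rec, _ = simulate_sts(StsSimConfig(seed=s, noise_gyro_sd=noise_sd))
                y, fs = preprocess_gyro(rec)
                hits += len(detect_sts_repetitions(y, fs)) == 5
            return hits

        rates = [hit_rate(sd) for sd in (0.05, 0.6, 1.2)]
        assert rates[0] >= rates[1] >= rates[2]


class TestTimeToReps:
    def test_noise_free_five_cycles_near_19s(self, clean_sts):
        rec, truth = clean_sts
        y, fs = preprocess_gyro(rec)
        events = detect_sts_repetitions(y, fs)
        assert time_to_reps(events, 5) == pytest.approx(19.0, abs=0.3)
        assert time_to_reps(events, 5) == pytest.approx(
            truth.true_time_to_n_reps_s, abs=0.1
        )

    def test_single_event_width_matches_gaussian_closed_form(self):
        # one symmetric stand/sit pair of unit-sigma Gaussian bumps: the
        # half-prominence width of each bump is 2*sigma*sqrt(2 ln 2), so the
        # n=1 duration is the peak gap plus two half-widths
        fs = 100.0
        t = np.arange(0, 20, 1 / fs)
        sigma, t_stand, t_sit = 0.5, 8.0, 11.0
        y = np.exp(-0.5 * ((t - t_stand) / sigma) ** 2)
        y -= np.exp(-0.5 * ((t - t_sit) / sigma) ** 2)
        events = detect_sts_repetitions(y, fs)
        assert len(events) == 1
        expected = (t_sit - t_stand) + 2 * sigma * np.sqrt(2 * np.log(2))
        assert time_to_reps(events, 1) == pytest.approx(expected, abs=0.05)

    def test_too_few_events_raises(self, clean_sts):
        rec, _ = clean_sts
        y, fs = preprocess_gyro(rec)
        events = detect_sts_repetitions(y, fs)[:4]
        with pytest.raises(TooFewRepsError):
            time_to_reps(events, 5)


class TestAnalyzeSts:
    def test_compliant_recording_is_valid(self):
        rec, truth = simulate_sts(StsSimConfig(seed=13))
        res = analyze_sts(rec)
        assert res.valid
        assert res.n_reps_detected == 5
        assert res.time_to_required_reps_s == pytest.approx(
            truth.true_time_to_n_reps_s, abs=0.25
        )

    def test_pure_stillness_is_invalid(self, sts_meta):
        rng = np.random.default_rng(4)
        n = 4000
        rec = InertialRecording(
            t=np.arange(n) / 100.0,
            accel=rng.normal(0, 0.02, (n, 3)) + np.array([0, 9.81, 0]),
            gyro=rng.normal(0, 0.05, (n, 3)),
            meta=sts_meta,
        )
        res = analyze_sts(rec)
        assert not res.valid
        assert res.failure_reason == StsFailure.TOO_FEW_REPS

    def test_truncated_recording_is_invalid(self, sts_meta):
        n = 50  # 0.5 s
        rec = InertialRecording(
            t=np.arange(n) / 100.0, accel=np.zeros((n, 3)),
            gyro=np.zeros((n, 3)), meta=sts_meta,
        )
        res = analyze_sts(rec)
        assert res.failure_reason == StsFailure.TOO_FEW_SAMPLES

    def test_movement_during_countdown_fails_baseline(self):
        rec, _ = simulate_sts(StsSimConfig(seed=17))
        gyro = rec.gyro.copy()
        gyro[:, 0] += 2.0 * np.sin(2 * np.pi * 1.0 * rec.t)  # restless countdown
        noisy = InertialRecording(
            t=rec.t, accel=rec.accel, gyro=gyro, mag=rec.mag, meta=rec.meta
        )
        assert analyze_sts(noisy).failure_reason == StsFailure.NO_STILL_BASELINE

    def test_wrong_trial_type_rejected(self):
        rec, _ = simulate_slb(SlbSimConfig(seed=1))
        with pytest.raises(UsageError):
            analyze_sts(rec)

    def test_extra_reps_counted_but_time_uses_first_five(self):
        cfg = StsSimConfig(n_reps=7, rep_cycle_mean_s=3.0, rep_cycle_sd_s=0.0,
                           noise_gyro_sd=0.0, noise_accel_sd=0.0, seed=0)
        rec, _ = simulate_sts(cfg)
        res = analyze_sts(rec)
        assert res.valid
        assert res.n_reps_detected == 7
        # first five 3-s cycles: onset-to-offset spans about 15 s
        assert res.time_to_required_reps_s == pytest.approx(15.0, abs=0.3)
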