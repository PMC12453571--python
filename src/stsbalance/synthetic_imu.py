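"""Synthetic smartphone-IMU recordings with known ground truth.

The study protocol this generator emulates: the participant presses start,
holds the phone to the chest through a 5-s audio countdown, performs the
activity (five sit-to-stand repetitions, or a single-leg stance held for up
to 30 s), then remains still for 5 s, presses stop (a brief handling
artifact), and remains still for another 5 s before the recording ends.

Signal models are deliberately minimal synthetic conventions, not validated
biomechanics:

* Sit-to-stand: the pitch (medio-lateral-axis) gyroscope carries one smooth
  positive Gaussian pulse per stand and one negative pulse per sit; the
  vertical accelerometer carries matching movement bursts on top of gravity.
* Single-leg balance sway: white Gaussian noise low-pass filtered to the
  configured bandwidth and rescaled so its RMS over the balance window
  equals the target exactly (an Ornstein-Uhlenbeck-like process), placed on
  the anterior-posterior and medio-lateral accelerometer axes.
* Foot contact: a 50-ms half-sine transient at the moment balance ends.

Every simulator returns the emitted recording together with a
:class:`GroundTruth` carrying the quantities the detectors are later asked
to recover. All randomness flows from the config's ``seed``; identical
config => identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from .errors import ConfigError
from .io_core import (
    DEFAULT_AXES,
    AxisConvention,
    InertialRecording,
    RecordingMetadata,
    TrialType,
)

__all__ = [
    "StsSimConfig",
    "SlbSimConfig",
    "CohortSimConfig",
    "GroundTruth",
    "simulate_sts",
    "simulate_slb",
    "simulate_cohort",
    "CohortSample",
]

_HALF_WIDTH = np.sqrt(2.0 * np.log(2.0))  # half-prominence half-width of a
# unit-sigma Gaussian pulse, in sigmas

#: Ambient magnetic field emitted on the magnetometer channels, uT.
_MAG_FIELD = np.array([20.0, -5.0, 43.0])


# ---------------------------------------------------------------------------
# Configs and truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StsSimConfig:
    """Sit-to-stand scenario parameters.

    ``rep_cycle_mean_s``/``rep_cycle_sd_s`` describe one full stand+sit
    cycle; the default 3.8 s mean puts five repetitions at 19 s, the
    neighbourhood of times reported for older adults on this test.
    ``peak_gyro_rad_s`` is the peak trunk pitch angular velocity of each
    movement phase. Noise SDs are white-sensor-noise levels; an SNR
    (peak / gyro noise SD) of 5 is a stressed but realistic phone recording.
    """

    n_reps: int = 5
    rep_cycle_mean_s: float = 3.8
    rep_cycle_sd_s: float = 0.3
    peak_gyro_rad_s: float = 1.5
    countdown_s: float = 5.0
    activity_cap_s: float = 30.0
    still_tail_s: float = 5.0
    press_artifact_s: float = 0.3
    noise_gyro_sd: float = 0.05
    noise_accel_sd: float = 0.02
    sample_rate_hz: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_reps < 1:
            raise ConfigError("n_reps must be >= 1")
        for name in ("rep_cycle_mean_s", "countdown_s", "activity_cap_s",
                     "still_tail_s", "sample_rate_hz"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")
        if self.rep_cycle_sd_s < 0 or self.noise_gyro_sd < 0 or self.noise_accel_sd < 0:
            raise ConfigError("SDs must be >= 0")
        if self.n_reps * self.rep_cycle_mean_s > self.activity_cap_s:
            raise ConfigError(
                f"{self.n_reps} reps of mean {self.rep_cycle_mean_s}s do not fit "
                f"in the {self.activity_cap_s}s activity window"
            )


@dataclass(frozen=True)
class SlbSimConfig:
    """Single-leg balance scenario parameters.

    The balance duration is drawn from a normal distribution truncated to
    ``(balance_min_s, activity_cap_s]``; the default mean of 13.7 s matches
    the holds typically observed in older adults, and the 6-s SD is a
    between-trial spread chosen as a synthetic convention. Set
    ``balance_duration_s`` to force an exact duration. ``spike_amplitude``
    is the peak of the 50-ms foot-contact transient; 0 means the foot never
    touches down and the full 30-s hold is emitted.
    """

    balance_mean_s: float = 13.7
    balance_sd_s: float = 6.0
    balance_min_s: float = 1.0
    balance_duration_s: Optional[float] = None
    sway_rms_ap: float = 0.05
    sway_rms_ml: float = 0.04
    sway_bandwidth_hz: float = 2.0
    spike_amplitude: float = 0.5
    countdown_s: float = 5.0
    activity_cap_s: float = 30.0
    still_tail_s: float = 5.0
    press_artifact_s: float = 0.3
    noise_accel_sd: float = 0.02
    noise_gyro_sd: float = 0.02
    sample_rate_hz: float = 100.0
    trial_type: TrialType = TrialType.SLB_LEFT
    seed: int = 0

    def validate(self) -> None:
        if self.sway_rms_ap < 0 or self.sway_rms_ml < 0:
            raise ConfigError("sway RMS targets must be >= 0")
        if not 0 < self.sway_bandwidth_hz < self.sample_rate_hz / 2:
            raise ConfigError("sway_bandwidth_hz must lie in (0, Nyquist)")
        if self.balance_duration_s is not None and not (
            0 < self.balance_duration_s <= self.activity_cap_s
        ):
            raise ConfigError("balance_duration_s must lie in (0, activity_cap_s]")
        for name in ("balance_mean_s", "countdown_s", "activity_cap_s",
                     "still_tail_s", "sample_rate_hz"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")
        if not TrialType(self.trial_type).is_slb:
            raise ConfigError("trial_type must be slb_left or slb_right")


@dataclass(frozen=True)
class CohortSimConfig:
    """Cohort-level schedule generator parameters.

    Participants are asked to complete one session of each activity per week
    for ``n_weeks`` weeks (the default 4-week, 17-participant cohort mirrors
    a small feasibility trial). Session days jitter around the weekly
    schedule; participants may miss a week, squeeze in an extra session, or
    drop out entirely partway through.
    """

    n_participants: int = 17
    n_weeks: int = 4
    target_sessions_per_week: int = 1
    gap_jitter_days: float = 1.5
    dropout_prob: float = 0.0
    missed_session_prob: float = 0.0
    extra_session_prob: float = 0.0
    start_date: str = "2023-01-02"
    sts: StsSimConfig = field(default_factory=StsSimConfig)
    slb: SlbSimConfig = field(default_factory=SlbSimConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1 or self.n_weeks < 1:
            raise ConfigError("n_participants and n_weeks must be >= 1")
        for name in ("dropout_prob", "missed_session_prob", "extra_session_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.gap_jitter_days < 0:
            raise ConfigError("gap_jitter_days must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Simulator-side truth against which the detectors are validated.

    Times in ``rep_event_times`` are absolute recording seconds;
    ``true_spike_time_s`` and ``true_balance_duration_s`` are seconds after
    the countdown ends (the clock the balance-duration measure uses).
    """

    rep_event_times: Tuple[Tuple[float, float], ...] = ()
    true_time_to_n_reps_s: Optional[float] = None
    true_balance_duration_s: Optional[float] = None
    true_spike_time_s: Optional[float] = None
    true_sway_rms_ap: Optional[float] = None
    true_sway_rms_ml: Optional[float] = None


# ---------------------------------------------------------------------------
# Sit-to-stand
# ---------------------------------------------------------------------------

def _gaussian_pulse(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def simulate_sts(
    cfg: StsSimConfig, axes: AxisConvention = DEFAULT_AXES, user_id: str = "sim",
    started_at: str = "2023-01-02T09:00:00",
) -> Tuple[InertialRecording, GroundTruth]:
    """Emit one sit-to-stand recording plus its ground truth.

    Per repetition the pitch gyro contains a positive pulse (stand) at 15% of
    the cycle and a negative pulse (sit) at 85%, each with sigma = cycle/8, so
    the half-prominence onset of the stand and offset of the sit fall at the
    cycle boundaries and the time over n repetitions approximates the summed
    cycle durations. The true time-to-n-reps is the closed-form span between
    those half-prominence crossings (first stand onset to n-th sit offset),
    matching the detector's duration convention.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate_hz

    cycles = rng.normal(cfg.rep_cycle_mean_s, cfg.rep_cycle_sd_s, size=cfg.n_reps)
    cycles = np.clip(cycles, 0.5 * cfg.rep_cycle_mean_s, 1.5 * cfg.rep_cycle_mean_s)
    activity_s = float(np.sum(cycles))
    if activity_s > cfg.activity_cap_s:
        raise ConfigError("drawn repetition cycles exceed the activity window")

    total_s = cfg.countdown_s + activity_s + 2 * cfg.still_tail_s + cfg.press_artifact_s
    n = int(round(total_s * fs))
    t = np.arange(n) / fs

    gyro = rng.normal(0.0, cfg.noise_gyro_sd, size=(n, 3))
    accel = rng.normal(0.0, cfg.noise_accel_sd, size=(n, 3))
    mag = _MAG_FIELD + rng.normal(0.0, 0.5, size=(n, 3))

    iv = AxisConvention.index(axes.vertical_axis)
    ip = AxisConvention.index(axes.pitch_gyro_axis)
    accel[:, iv] += 9.81  # chest-held, long axis up: reaction to gravity

    events: List[Tuple[float, float]] = []
    start = cfg.countdown_s
    pitch = np.zeros(n)
    burst = np.zeros(n)
    sigmas: List[Tuple[float, float]] = []
    for d in cycles:
        t_stand = start + 0.15 * d
        t_sit = start + 0.85 * d
        sigma = d / 8.0
        pitch += cfg.peak_gyro_rad_s * _gaussian_pulse(t, t_stand, sigma)
        pitch -= cfg.peak_gyro_rad_s * _gaussian_pulse(t, t_sit, sigma)
        # vertical movement burst: derivative-of-Gaussian around each phase
        for tc, sgn in ((t_stand, +1.0), (t_sit, -1.0)):
            burst += sgn * 1.2 * (t - tc) / sigma * _gaussian_pulse(t, tc, sigma)
        events.append((t_stand, t_sit))
        sigmas.append((sigma, sigma))
        start += d

    gyro[:, ip] += pitch
    accel[:, iv] += burst

    _add_press_artifact(
        accel, gyro, t, cfg.countdown_s + activity_s + cfg.still_tail_s,
        cfg.press_artifact_s, rng,
    )

    hw_first = sigmas[0][0] * _HALF_WIDTH
    hw_last = sigmas[cfg.n_reps - 1][1] * _HALF_WIDTH
    true_time = (events[-1][1] + hw_last) - (events[0][0] - hw_first)

    meta = RecordingMetadata(
        user_id=user_id, trial_type=TrialType.STS, started_at=started_at,
        sample_rate_hz=fs, device_label="synthetic",
    )
    rec = InertialRecording(t=t, accel=accel, gyro=gyro, mag=mag, meta=meta)
    truth = GroundTruth(
        rep_event_times=tuple(events),
        true_time_to_n_reps_s=float(true_time),
    )
    return rec, truth


def _add_press_artifact(
    accel: np.ndarray, gyro: np.ndarray, t: np.ndarray, t0: float,
    dur: float, rng: np.random.Generator,
) -> None:
    """Short high-frequency handling burst when the stop button is pressed."""
    if dur <= 0:
        return
    mask = (t >= t0) & (t < t0 + dur)
    if not np.any(mask):
        return
    tt = t[mask] - t0
    window = np.sin(np.pi * tt / dur) ** 2
    carrier = np.sin(2 * np.pi * 25.0 * tt)
    accel[mask] += (3.0 * window * carrier)[:, None] * rng.uniform(0.6, 1.0, size=3)
    gyro[mask] += (0.4 * window * carrier)[:, None] * rng.uniform(0.6, 1.0, size=3)


# ---------------------------------------------------------------------------
# Single-leg balance
# ---------------------------------------------------------------------------

def _sway_track(
    n: int, fs: float, bandwidth_hz: float, rms: float, rng: np.random.Generator
) -> np.ndarray:
    """Low-pass-filtered Gaussian noise rescaled to an exact target RMS."""
    if rms == 0.0 or n == 0:
        return np.zeros(n)
    white = rng.normal(0.0, 1.0, size=n + int(4 * fs))  # pad for filter warm-up
    # order 4: keeps the sway spectrum genuinely inside its nominal bandwidth
    sos = sps.butter(4, bandwidth_hz, btype="low", fs=fs, output="sos")
    x = sps.sosfilt(sos, white)[-n:]
    x = x - np.mean(x)
    # half-cosine build-up over the first 0.5 s: the sway grows as the foot
    # leaves the floor rather than switching on as a broadband step edge
    n_ramp = min(n, int(round(0.5 * fs)))
    if n_ramp > 1:
        x[:n_ramp] *= 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    cur = np.sqrt(np.mean(x**2))
    if cur == 0.0:
        return np.zeros(n)
    return x * (rms / cur)


def simulate_slb(
    cfg: SlbSimConfig, axes: AxisConvention = DEFAULT_AXES, user_id: str = "sim",
    started_at: str = "2023-01-02T09:05:00",
) -> Tuple[InertialRecording, GroundTruth]:
    """Emit one single-leg balance recording plus its ground truth.

    Sway occupies the AP/ML accelerometer axes during the balance window and
    has *exactly* the configured RMS over that window. If the hold ends
    before the 30-s cap a half-sine foot-contact spike is superposed at the
    contact instant (AP axis, with a 60% echo on ML), after which the signal
    is quiet standing (sensor noise only).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate_hz

    if cfg.spike_amplitude == 0.0:
        dur = cfg.activity_cap_s
    elif cfg.balance_duration_s is not None:
        dur = float(cfg.balance_duration_s)
    else:
        a = (cfg.balance_min_s - cfg.balance_mean_s) / cfg.balance_sd_s
        b = (cfg.activity_cap_s - cfg.balance_mean_s) / cfg.balance_sd_s
        dur = float(
            spstats.truncnorm.rvs(
                a, b, loc=cfg.balance_mean_s, scale=cfg.balance_sd_s,
                random_state=rng,
            )
        )
    contact = dur < cfg.activity_cap_s and cfg.spike_amplitude > 0.0

    total_s = cfg.countdown_s + dur + 2 * cfg.still_tail_s + cfg.press_artifact_s
    n = int(round(total_s * fs))
    t = np.arange(n) / fs

    accel = rng.normal(0.0, cfg.noise_accel_sd, size=(n, 3))
    gyro = rng.normal(0.0, cfg.noise_gyro_sd, size=(n, 3))
    mag = _MAG_FIELD + rng.normal(0.0, 0.5, size=(n, 3))

    iv = AxisConvention.index(axes.vertical_axis)
    iap = AxisConvention.index(axes.ap_axis)
    iml = AxisConvention.index(axes.ml_axis)
    accel[:, iv] += 9.81

    i0 = int(round(cfg.countdown_s * fs))
    i1 = int(round((cfg.countdown_s + dur) * fs))
    nbal = i1 - i0
    accel[i0:i1, iap] += _sway_track(nbal, fs, cfg.sway_bandwidth_hz, cfg.sway_rms_ap, rng)
    accel[i0:i1, iml] += _sway_track(nbal, fs, cfg.sway_bandwidth_hz, cfg.sway_rms_ml, rng)

    spike_time = None
    if contact:
        spike_time = dur  # seconds after countdown end
        t_abs = cfg.countdown_s + dur
        width = 0.05  # the 50-ms impact transient follows the contact instant
        mask = (t >= t_abs) & (t < t_abs + width)
        tt = t[mask] - t_abs
        pulse = cfg.spike_amplitude * np.sin(np.pi * tt / width)
        accel[mask, iap] += pulse
        accel[mask, iml] += 0.6 * pulse

    _add_press_artifact(
        accel, gyro, t, cfg.countdown_s + dur + cfg.still_tail_s,
        cfg.press_artifact_s, rng,
    )

    meta = RecordingMetadata(
        user_id=user_id, trial_type=TrialType(cfg.trial_type),
        started_at=started_at, sample_rate_hz=fs, device_label="synthetic",
    )
    rec = InertialRecording(t=t, accel=accel, gyro=gyro, mag=mag, meta=meta)
    truth = GroundTruth(
        true_balance_duration_s=float(dur),
        true_spike_time_s=spike_time,
        true_sway_rms_ap=cfg.sway_rms_ap,
        true_sway_rms_ml=cfg.sway_rms_ml,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortSample:
    """One simulated cohort: session log plus per-recording material."""

    log: pd.DataFrame  # participant_id, activity, session_datetime, recording_key
    recordings: "dict[str, tuple[InertialRecording, GroundTruth]]"


def _session_days(cfg: CohortSimConfig, rng: np.random.Generator) -> List[int]:
    """Jittered weekly schedule for one participant, in days from start."""
    if rng.random() < cfg.dropout_prob:
        dropout_week = int(rng.integers(1, cfg.n_weeks + 1))
    else:
        dropout_week = cfg.n_weeks + 1

    days: List[int] = []
    prev = 0
    for week in range(1, cfg.n_weeks + 1):
        if week >= dropout_week:
            break
        n_sessions = cfg.target_sessions_per_week
        if rng.random() < cfg.missed_session_prob:
            n_sessions -= 1
        if rng.random() < cfg.extra_session_prob:
            n_sessions += 1
        for k in range(n_sessions):
            day = 7 * week + int(round(rng.normal(0.0, cfg.gap_jitter_days))) + 3 * k
            day = max(prev + 1, day)
            days.append(day)
            prev = day
    return days


def simulate_cohort(
    cfg: CohortSimConfig,
    axes: AxisConvention = DEFAULT_AXES,
    with_recordings: bool = True,
) -> CohortSample:
    """Simulate a cohort's worth of weekly assessment sessions.

    Each session day carries one sit-to-stand recording and a left+right pair
    of balance recordings (one log row per activity per session; the two leg
    recordings share the session's ``slb`` row, referenced by key suffixes).
    With ``with_recordings=False`` only the log and per-session truths are
    produced, which keeps large schedule-level Monte Carlo runs cheap.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    start = pd.Timestamp(cfg.start_date)

    rows = []
    recordings: "dict[str, tuple[InertialRecording, GroundTruth]]" = {}
    for p in range(cfg.n_participants):
        pid = f"P{p + 1:02d}"
        for s_idx, day in enumerate(_session_days(cfg, rng)):
            when = start + pd.Timedelta(days=day, hours=9)
            iso = when.isoformat()
            sts_key = f"{pid}_s{s_idx}_sts"
            slb_keys = [f"{pid}_s{s_idx}_slb_left", f"{pid}_s{s_idx}_slb_right"]
            rows.append((pid, "sts", when, sts_key))
            rows.append((pid, "slb", when, ";".join(slb_keys)))
            if with_recordings:
                sub = int(rng.integers(0, 2**31 - 1))
                from dataclasses import replace as _rp

                recordings[sts_key] = simulate_sts(
                    _rp(cfg.sts, seed=sub), axes, user_id=pid, started_at=iso,
                )
                for leg, key in zip((TrialType.SLB_LEFT, TrialType.SLB_RIGHT), slb_keys):
                    sub = int(rng.integers(0, 2**31 - 1))
                    recordings[key] = simulate_slb(
                        _rp(cfg.slb, seed=sub, trial_type=leg), axes,
                        user_id=pid, started_at=iso,
                    )

    log = pd.DataFrame(
        rows, columns=["participant_id", "activity", "session_datetime", "recording_key"]
    )
    return CohortSample(log=log, recordings=recordings)
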