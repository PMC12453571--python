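"""Sit-to-stand analysis: gyroscope preprocessing, repetition peak detection,
and the time to complete the required number of repetitions.

The chair-rise test is captured by the trunk pitch angular velocity: standing
up produces a positive swing of the medio-lateral-axis gyroscope, sitting
back down a negative swing. The pipeline low-pass filters the pitch channel
(zero phase, so peak times are not shifted), removes the still-countdown
baseline, finds alternating positive/negative extrema by prominence-based
peak detection, pairs them into (stand, sit) repetitions, and reports the
time from the onset of the first stand to the offset of the n-th sit, where
onset/offset are the half-prominence crossings flanking each peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal as sps

from .errors import UsageError
from .io_core import (
    DEFAULT_AXES,
    AxisConvention,
    InertialRecording,
    TrialType,
    resample_uniform,
)

__all__ = [
    "StsParams",
    "StsFailure",
    "RepEvent",
    "StsResult",
    "preprocess_gyro",
    "detect_sts_repetitions",
    "time_to_reps",
    "analyze_sts",
    "TooFewRepsError",
]


class TooFewRepsError(ValueError):
    """Fewer repetitions detected than requested."""


@dataclass(frozen=True)
class StsParams:
    """Tunables of the sit-to-stand detector.

    ``min_peak_prominence_frac`` is relative to the robust signal range
    (0.1th-99.9th percentile span), which makes detection invariant to the
    overall amplitude scale. ``min_peak_snr`` is an additional adaptive
    floor — a candidate peak's prominence must also exceed this multiple of
    the robust noise scale estimated from the still countdown segment — so
    that a recording containing nothing but sensor noise yields no
    repetitions no matter how the range-relative threshold scales.
    """

    lowpass_cutoff_hz: float = 5.0
    filter_order: int = 4
    min_peak_prominence_frac: float = 0.3
    min_peak_snr: float = 8.0
    min_inter_peak_s: float = 0.8
    required_reps: int = 5
    still_window_s: float = 1.0
    still_var_threshold: float = 0.05  # (rad/s)^2, on the filtered signal
    countdown_s: float = 5.0

    def validate(self, fs: float) -> None:
        if not 0 < self.lowpass_cutoff_hz < fs / 2:
            raise ValueError("lowpass_cutoff_hz must lie in (0, Nyquist)")
        if not 0 < self.min_peak_prominence_frac <= 1:
            raise ValueError("min_peak_prominence_frac must lie in (0, 1]")
        if self.min_inter_peak_s <= 0:
            raise ValueError("min_inter_peak_s must be > 0")


class StsFailure(str, Enum):
    NONE = "none"
    TOO_FEW_SAMPLES = "too_few_samples"
    TOO_FEW_REPS = "too_few_reps"
    NO_STILL_BASELINE = "no_still_baseline"
    NONUNIFORM_SAMPLING = "nonuniform_sampling"


@dataclass(frozen=True)
class RepEvent:
    """One repetition: a stand peak followed by a sit peak.

    Peak times locate the extrema of the filtered pitch signal; onset/offset
    are the half-prominence crossings immediately flanking the stand (left
    side) and sit (right side) peaks — proxies for movement start and end.
    """

    stand_peak_s: float
    sit_peak_s: float
    stand_onset_s: float
    sit_offset_s: float


@dataclass(frozen=True)
class StsResult:
    valid: bool
    n_reps_detected: int
    rep_events: Tuple[RepEvent, ...]
    time_to_required_reps_s: Optional[float]
    failure_reason: StsFailure

    def __post_init__(self) -> None:
        assert self.valid == (self.failure_reason == StsFailure.NONE)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess_gyro(
    rec: InertialRecording,
    axes: AxisConvention = DEFAULT_AXES,
    params: StsParams = StsParams(),
) -> Tuple[np.ndarray, float]:
    """Zero-phase low-pass filtered, baseline-removed pitch angular velocity.

    Returns ``(signal, fs)``. The baseline is the mean of the first
    ``still_window_s`` of the countdown (the participant sits still through
    the countdown, so this window estimates the gyro's resting offset).
    Raises ``ValueError`` when the recording is shorter than two still
    windows.
    """
    if not rec.is_uniform():
        rec = resample_uniform(rec)
    fs = rec.meta.sample_rate_hz
    params.validate(fs)
    if rec.duration_s < 2 * params.still_window_s:
        raise ValueError("recording shorter than two still windows")

    x = rec.axis("gyro", axes.pitch_gyro_axis)
    sos = sps.butter(
        params.filter_order, params.lowpass_cutoff_hz, btype="low", fs=fs, output="sos"
    )
    y = sps.sosfiltfilt(sos, x)
    n_still = max(2, int(round(params.still_window_s * fs)))
    y = y - float(np.mean(y[:n_still]))
    return y, fs


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------

def _robust_range(y: np.ndarray) -> float:
    lo, hi = np.percentile(y, [0.1, 99.9])
    return float(hi - lo)


def _mad_scale(y: np.ndarray) -> float:
    return float(1.4826 * np.median(np.abs(y - np.median(y))))


def _half_prominence_crossing(
    y: np.ndarray, peak: int, prom: float, side: str, fs: float
) -> float:
    """Time where the signal crosses (peak height - prom/2) on one side."""
    ref = y[peak] - 0.5 * prom
    idx = peak
    if side == "left":
        while idx > 0 and y[idx] > ref:
            idx -= 1
        if y[idx] > ref:  # ran off the edge
            return idx / fs
        # linear interpolation between idx and idx+1
        frac = (ref - y[idx]) / (y[idx + 1] - y[idx])
        return (idx + frac) / fs
    else:
        n = len(y)
        while idx < n - 1 and y[idx] > ref:
            idx += 1
        if y[idx] > ref:
            return idx / fs
        frac = (y[idx - 1] - ref) / (y[idx - 1] - y[idx])
        return (idx - 1 + frac) / fs


def detect_sts_repetitions(
    y: np.ndarray, fs: float, params: StsParams = StsParams()
) -> List[RepEvent]:
    """Pair alternating stand(+)/sit(-) extrema into repetition events.

    A candidate extremum must clear both the range-relative prominence
    threshold and the countdown-noise floor, and be at least
    ``min_inter_peak_s`` from its neighbours of the same sign. Runs of
    same-sign extrema keep the largest. A trailing unpaired stand is not a
    repetition. An empty list is a legal result.
    """
    y = np.asarray(y, dtype=float)
    rng_ = _robust_range(y)
    if rng_ <= 0 or not np.isfinite(rng_):
        return []
    n_still = max(2, int(round(params.still_window_s * fs)))
    noise_scale = _mad_scale(y[:n_still])
    threshold = max(
        params.min_peak_prominence_frac * rng_,
        params.min_peak_snr * noise_scale,
    )
    distance = max(1, int(round(params.min_inter_peak_s * fs)))

    pos, pos_props = sps.find_peaks(y, prominence=threshold, distance=distance)
    neg, neg_props = sps.find_peaks(-y, prominence=threshold, distance=distance)

    # merge, enforce alternation (keep the larger of same-sign runs)
    merged: List[Tuple[int, int, float]] = []  # (index, sign, prominence)
    cand = sorted(
        [(int(i), +1, float(p)) for i, p in zip(pos, pos_props["prominences"])]
        + [(int(i), -1, float(p)) for i, p in zip(neg, neg_props["prominences"])]
    )
    for idx, sign, prom in cand:
        if merged and merged[-1][1] == sign:
            if abs(y[idx]) > abs(y[merged[-1][0]]):
                merged[-1] = (idx, sign, prom)
        else:
            merged.append((idx, sign, prom))

    # drop leading sit so pairing starts on a stand
    if merged and merged[0][1] == -1:
        merged = merged[1:]

    events: List[RepEvent] = []
    for k in range(0, len(merged) - 1, 2):
        (i_st, s_st, _p_st), (i_si, s_si, _p_si) = merged[k], merged[k + 1]
        if s_st != +1 or s_si != -1:  # alternation already enforced; safety
            continue
        # crossings use the height above the (zero) still baseline as the
        # prominence: less noise-sensitive than the contour-line estimate
        onset = _half_prominence_crossing(y, i_st, y[i_st], "left", fs)
        offset = _half_prominence_crossing(-y, i_si, -y[i_si], "right", fs)
        events.append(
            RepEvent(
                stand_peak_s=i_st / fs,
                sit_peak_s=i_si / fs,
                stand_onset_s=onset,
                sit_offset_s=offset,
            )
        )
    return events


def time_to_reps(events: List[RepEvent], n: int) -> float:
    """Seconds from the first stand's onset to the n-th sit's offset."""
    if len(events) < n:
        raise TooFewRepsError(f"need {n} repetitions, detected {len(events)}")
    if n < 1:
        raise ValueError("n must be >= 1")
    return events[n - 1].sit_offset_s - events[0].stand_onset_s


# ---------------------------------------------------------------------------
# End-to-end
# ---------------------------------------------------------------------------

def analyze_sts(
    rec: InertialRecording,
    axes: AxisConvention = DEFAULT_AXES,
    params: StsParams = StsParams(),
) -> StsResult:
    """Run the full sit-to-stand pipeline on one recording.

    Validity requires a still countdown baseline (filtered-signal variance in
    the first still window below ``still_var_threshold``) and at least
    ``required_reps`` detected repetitions; extra repetitions beyond the
    requirement are counted but the duration uses the first ``required_reps``.
    """
    if rec.meta.trial_type != TrialType.STS:
        raise UsageError(
            f"analyze_sts expects an sts recording, got {rec.meta.trial_type.value}"
        )

    def fail(reason: StsFailure, events: Tuple[RepEvent, ...] = ()) -> StsResult:
        return StsResult(
            valid=False, n_reps_detected=len(events), rep_events=events,
            time_to_required_reps_s=None, failure_reason=reason,
        )

    if not rec.is_uniform():
        try:
            rec = resample_uniform(rec)
        except Exception:
            return fail(StsFailure.NONUNIFORM_SAMPLING)

    try:
        y, fs = preprocess_gyro(rec, axes, params)
    except ValueError:
        return fail(StsFailure.TOO_FEW_SAMPLES)

    n_still = max(2, int(round(params.still_window_s * fs)))
    if float(np.var(y[:n_still])) > params.still_var_threshold:
        return fail(StsFailure.NO_STILL_BASELINE)

    events = tuple(detect_sts_repetitions(y, fs, params))
    if len(events) < params.required_reps:
        return fail(StsFailure.TOO_FEW_REPS, events)

    t_req = time_to_reps(list(events), params.required_reps)
    return StsResult(
        valid=True,
        n_reps_detected=len(events),
        rep_events=events,
        time_to_required_reps_s=float(t_req),
        failure_reason=StsFailure.NONE,
    )
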