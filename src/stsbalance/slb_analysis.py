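"""Single-leg balance analysis: postural sway magnitude, foot-contact spike
detection, balance duration, and the data-sufficiency validity gate.

During a one-legged stance the chest-held accelerometer's anterior-posterior
(AP) and medio-lateral (ML) axes carry the body's sway. The pipeline
band-passes those channels (zero phase), detects the moment the raised foot
strikes the floor as the first exceedance of an adaptive threshold — a
multiple of the robust (MAD-based) sway scale estimated early in the stance —
computes the balance duration (capped at the 30-s protocol limit), and, when
the hold provides enough data (>= 11 s by default), summarises sway as RMS
per axis, resultant RMS, and path length over the balance window.

Impact transients are broadband while postural sway is confined below a few
hertz, so spike detection runs on a high band (default 8-25 Hz) where the
baseline is sensor noise and the sway itself cannot trip the threshold; the
sway metrics use the conventional posturography band (default 0.1-3 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Tuple

import numpy as np
from scipy import signal as sps

from .errors import InsufficientDataError, UsageError
from .io_core import (
    DEFAULT_AXES,
    AxisConvention,
    InertialRecording,
    resample_uniform,
)

__all__ = [
    "SlbParams",
    "SlbFailure",
    "SwayMetrics",
    "SlbResult",
    "extract_sway",
    "detect_foot_contact",
    "balance_duration",
    "classify_validity",
    "analyze_slb",
]


@dataclass(frozen=True)
class SlbParams:
    """Tunables of the balance analysis.

    ``min_analysis_s`` is the data-sufficiency gate: holds shorter than this
    do not provide enough samples for stable sway statistics and are flagged
    invalid. ``spike_threshold_k`` scales the adaptive foot-contact threshold
    (multiples of the MAD-based sway scale of the baseline window).
    """

    sway_band_hz: Tuple[float, float] = (0.1, 3.0)
    spike_band_hz: Tuple[float, float] = (8.0, 25.0)
    filter_order: int = 2
    spike_threshold_k: float = 6.0
    spike_min_duration_s: float = 0.05
    baseline_window_s: float = 5.0
    min_baseline_s: float = 1.0
    min_analysis_s: float = 11.0
    activity_cap_s: float = 30.0
    countdown_s: float = 5.0

    def validate(self, fs: float) -> None:
        for lo, hi in (self.sway_band_hz, self.spike_band_hz):
            if not 0 <= lo < hi < fs / 2:
                raise ValueError(f"band ({lo}, {hi}) must satisfy 0 <= lo < hi < Nyquist")
        if self.spike_threshold_k <= 1:
            raise ValueError("spike_threshold_k must be > 1")
        if self.min_analysis_s <= 0:
            raise ValueError("min_analysis_s must be > 0")


class SlbFailure(str, Enum):
    NONE = "none"
    INSUFFICIENT_DURATION = "insufficient_duration"
    TOO_FEW_SAMPLES = "too_few_samples"
    NO_COUNTDOWN_BASELINE = "no_countdown_baseline"


@dataclass(frozen=True)
class SwayMetrics:
    """Sway summary over the balance window. RMS values in m/s^2.

    ``path_length`` is the integrated point-to-point excursion in the AP-ML
    acceleration plane (sum of sample-to-sample Euclidean increments).
    ``rms_resultant`` = sqrt(rms_ap^2 + rms_ml^2) is the headline magnitude.
    """

    rms_ap: float
    rms_ml: float
    rms_resultant: float
    path_length: float


@dataclass(frozen=True)
class SlbResult:
    valid: bool
    balance_duration_s: Optional[float]
    foot_contact_time_s: Optional[float]
    sway: Optional[SwayMetrics]
    failure_reason: SlbFailure

    def __post_init__(self) -> None:
        assert self.valid == (self.failure_reason == SlbFailure.NONE)
        assert (self.sway is not None) == self.valid


# ---------------------------------------------------------------------------
# Sway extraction
# ---------------------------------------------------------------------------

def _bandpass(x: np.ndarray, fs: float, band: Tuple[float, float], order: int) -> np.ndarray:
    # forward-backward filtering applies the response twice; widen the design
    # corners by the dual-pass correction so the -3 dB points of the combined
    # filter land on the nominal band edges (Winter's correction,
    # c = (sqrt(2)-1)^(1/(2*order)) for a Butterworth)
    c = (np.sqrt(2.0) - 1.0) ** (1.0 / (2 * order))
    lo, hi = band[0] * c, min(band[1] / c, 0.999 * fs / 2)
    sos = sps.butter(order, (lo, hi), btype="bandpass", fs=fs, output="sos")
    padlen = 3 * (2 * order + 1)
    if len(x) <= padlen:
        raise InsufficientDataError(
            f"signal of {len(x)} samples too short for zero-phase filtering"
        )
    return sps.sosfiltfilt(sos, x)


def extract_sway(
    rec: InertialRecording,
    axes: AxisConvention = DEFAULT_AXES,
    params: SlbParams = SlbParams(),
    band: Optional[Tuple[float, float]] = None,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Band-passed AP and ML acceleration; returns ``(ap, ml, fs)``.

    Gravity and slow postural drift are rejected by the band's low corner;
    ``band`` defaults to the sway analysis band and can be overridden (the
    foot-contact detector uses the wider spike band).
    """
    if not rec.is_uniform():
        rec = resample_uniform(rec)
    fs = rec.meta.sample_rate_hz
    params.validate(fs)
    b = band if band is not None else params.sway_band_hz
    ap = _bandpass(rec.axis("accel", axes.ap_axis), fs, b, params.filter_order)
    ml = _bandpass(rec.axis("accel", axes.ml_axis), fs, b, params.filter_order)
    return ap, ml, fs


# ---------------------------------------------------------------------------
# Foot contact & duration
# ---------------------------------------------------------------------------

def detect_foot_contact(
    ap: np.ndarray, ml: np.ndarray, fs: float, params: SlbParams = SlbParams()
) -> Optional[float]:
    """First threshold exceedance of the resultant sway after the countdown.

    The baseline robust scale is the MAD-based scale of the resultant over
    the first ``baseline_window_s`` after the countdown ends (robust to a
    spike falling inside the window on very short holds). An exceedance only
    counts when sustained for ``spike_min_duration_s`` — a foot strike rings
    for tens of milliseconds, an isolated noise sample does not. The reported
    contact time is the resultant's peak within the first sustained
    exceedance event (merging sub-0.1-s dropouts), which is insensitive to
    the exact threshold level. Returns seconds after countdown end, or None
    if the threshold is never exceeded.
    """
    i0 = int(round(params.countdown_s * fs))
    if len(ap) - i0 < int(round(params.min_baseline_s * fs)):
        raise InsufficientDataError("no post-countdown baseline window available")
    r = np.hypot(ap[i0:], ml[i0:])
    nb = min(len(r), int(round(params.baseline_window_s * fs)))
    base = r[:nb]
    scale = float(1.4826 * np.median(np.abs(base - np.median(base))))
    if scale <= 0:
        scale = float(np.std(base)) or 1e-12
    above = r > params.spike_threshold_k * scale
    # the band-passed impact rings: its resultant dips at ring zero
    # crossings, so close sub-20-ms dropouts before measuring run length
    close = int(round(0.02 * fs))
    if close > 0 and above.any():
        idx = np.nonzero(above)[0]
        gaps = np.diff(idx)
        closed = above.copy()
        for k_, g in enumerate(gaps):
            if 1 < g <= close + 1:
                closed[idx[k_]: idx[k_ + 1]] = True
        above = closed
    need = max(1, int(round(params.spike_min_duration_s * fs)))
    if need > 1:
        run = np.convolve(above.astype(int), np.ones(need, dtype=int), mode="valid")
        starts = np.nonzero(run == need)[0]
    else:
        starts = np.nonzero(above)[0]
    if starts.size == 0:
        return None
    start = int(starts[0])
    # extend the event across the exceedances, merging gaps shorter than 0.1 s
    gap_max = int(round(0.1 * fs))
    idx = np.nonzero(above)[0]
    idx = idx[idx >= start]
    end = start
    for j in idx:
        if j - end > gap_max:
            break
        end = j
    peak = start + int(np.argmax(r[start:end + 1]))
    return float(peak / fs)


def balance_duration(
    contact_time_s: Optional[float], params: SlbParams = SlbParams()
) -> float:
    """Seconds of maintained stance: the contact time, else the 30-s cap.

    Spuriously late contacts (inside the post-activity still tails) are
    clipped to the cap.
    """
    if contact_time_s is None:
        return float(params.activity_cap_s)
    return float(min(contact_time_s, params.activity_cap_s))


def classify_validity(duration_s: float, params: SlbParams = SlbParams()) -> bool:
    """Data-sufficiency gate: the sway measures need >= ``min_analysis_s``
    of stance data. Exactly thresholded: duration >= gate <=> valid."""
    return duration_s >= params.min_analysis_s


# ---------------------------------------------------------------------------
# End-to-end
# ---------------------------------------------------------------------------

def _sway_metrics(ap: np.ndarray, ml: np.ndarray) -> SwayMetrics:
    rms_ap = float(np.sqrt(np.mean(ap**2)))
    rms_ml = float(np.sqrt(np.mean(ml**2)))
    return SwayMetrics(
        rms_ap=rms_ap,
        rms_ml=rms_ml,
        rms_resultant=float(np.hypot(rms_ap, rms_ml)),
        path_length=float(np.sum(np.hypot(np.diff(ap), np.diff(ml)))),
    )


def analyze_slb(
    rec: InertialRecording,
    axes: AxisConvention = DEFAULT_AXES,
    params: SlbParams = SlbParams(),
) -> SlbResult:
    """Run the full balance pipeline on one recording.

    Foot contact is detected on the wide spike band; when the hold passes the
    sufficiency gate, sway metrics are computed on the sway band over
    [countdown end, countdown end + balance duration).
    """
    if not rec.meta.trial_type.is_slb:
        raise UsageError(
            f"analyze_slb expects an slb recording, got {rec.meta.trial_type.value}"
        )

    def fail(reason: SlbFailure, dur: Optional[float] = None,
             contact: Optional[float] = None) -> SlbResult:
        return SlbResult(
            valid=False, balance_duration_s=dur, foot_contact_time_s=contact,
            sway=None, failure_reason=reason,
        )

    if not rec.is_uniform():
        rec = resample_uniform(rec)
    fs = rec.meta.sample_rate_hz
    try:
        params.validate(fs)
        ap_w, ml_w, _ = extract_sway(rec, axes, params, band=params.spike_band_hz)
    except InsufficientDataError:
        return fail(SlbFailure.TOO_FEW_SAMPLES)

    try:
        contact = detect_foot_contact(ap_w, ml_w, fs, params)
    except InsufficientDataError:
        return fail(SlbFailure.NO_COUNTDOWN_BASELINE)

    # available stance data cannot exceed what was recorded after countdown
    avail = rec.duration_s - params.countdown_s
    dur = min(balance_duration(contact, params), max(avail, 0.0))
    if not classify_validity(dur, params):
        return fail(SlbFailure.INSUFFICIENT_DURATION, dur=dur, contact=contact)

    ap, ml, _ = extract_sway(rec, axes, params)
    i0 = int(round(params.countdown_s * fs))
    i1 = i0 + int(round(dur * fs))
    metrics = _sway_metrics(ap[i0:i1], ml[i0:i1])
    return SlbResult(
        valid=True,
        balance_duration_s=float(dur),
        foot_contact_time_s=contact,
        sway=metrics,
        failure_reason=SlbFailure.NONE,
    )
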