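"""Recording data model, on-disk format, and basic signal conditioning.

A recording is a time-stamped set of tri-axial inertial streams captured by a
smartphone held in portrait orientation against the chest: accelerometer
(m/s^2), gyroscope (rad/s) and, optionally, magnetometer (uT), nominally
sampled at 100 Hz. On disk a recording is a plain CSV
(``t,ax,ay,az,gx,gy,gz[,mx,my,mz]``) plus a JSON metadata sidecar
(``<stem>.json``) declaring the trial type, user, nominal sample rate and the
units the CSV columns are expressed in. Readers convert declared units to the
canonical internal convention (m/s^2, rad/s, uT) so every downstream
algorithm sees one unit system.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, ConsistencyError, FormatError, InsufficientDataError

__all__ = [
    "TrialType",
    "RecordingMetadata",
    "InertialRecording",
    "AxisConvention",
    "DEFAULT_AXES",
    "read_recording",
    "write_recording",
    "resample_uniform",
]

#: Gravitational acceleration used for unit conversion from g (standard value).
GRAVITY_M_S2 = 9.80665

#: Tolerated relative deviation of the median sample interval from nominal.
TIMING_JITTER_TOL = 0.05

_CSV_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
_MAG_COLUMNS = ["mx", "my", "mz"]

_ACCEL_UNIT_FACTORS = {"m/s^2": 1.0, "m/s2": 1.0, "g": GRAVITY_M_S2}
_GYRO_UNIT_FACTORS = {"rad/s": 1.0, "deg/s": math.pi / 180.0}


class TrialType(str, Enum):
    """Kind of functional assessment a recording belongs to."""

    STS = "sts"
    SLB_LEFT = "slb_left"
    SLB_RIGHT = "slb_right"

    @property
    def is_slb(self) -> bool:
        return self in (TrialType.SLB_LEFT, TrialType.SLB_RIGHT)


@dataclass(frozen=True)
class RecordingMetadata:
    """Trial metadata attached to every recording."""

    user_id: str
    trial_type: TrialType
    started_at: str  # ISO-8601
    sample_rate_hz: float = 100.0
    device_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "trial_type", TrialType(self.trial_type))
        if not self.sample_rate_hz > 0:
            raise FormatError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")


@dataclass(frozen=True)
class AxisConvention:
    """Mapping from device axes to body axes for the chest-held portrait grip.

    With the phone held portrait against the sternum (long axis vertical,
    screen facing the chest), the device long axis is head-ward (vertical),
    the screen normal is anterior-posterior (AP), and the remaining axis is
    medio-lateral (ML). Trunk flexion/extension (pitch) is rotation about the
    ML axis, so the pitch gyro channel is the ML gyro axis.
    """

    vertical_axis: str = "y"
    ap_axis: str = "z"
    ml_axis: str = "x"
    pitch_gyro_axis: str = "x"

    def __post_init__(self) -> None:
        axes = {self.vertical_axis, self.ap_axis, self.ml_axis}
        if axes != {"x", "y", "z"}:
            raise FormatError(
                f"vertical/ap/ml axes must be a permutation of x,y,z, got {axes}"
            )
        if self.pitch_gyro_axis not in ("x", "y", "z"):
            raise FormatError(f"bad pitch_gyro_axis {self.pitch_gyro_axis!r}")

    @staticmethod
    def index(axis: str) -> int:
        return "xyz".index(axis)


DEFAULT_AXES = AxisConvention()


@dataclass
class InertialRecording:
    """In-memory recording: uniform-unit channel arrays plus metadata.

    ``t`` is seconds from the first retained sample (the recording includes
    the 5-s countdown; t=0 is the moment the app starts sampling).
    ``accel``/``gyro``/``mag`` are (n, 3) arrays in device-axis order x,y,z,
    in m/s^2, rad/s and uT respectively; ``mag`` may be None.
    """

    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    meta: RecordingMetadata
    mag: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.mag is not None:
            self.mag = np.asarray(self.mag, dtype=float)
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        n = self.t.shape[0]
        if n < 1:
            raise FormatError("recording must contain at least one sample")
        for name, arr in (("accel", self.accel), ("gyro", self.gyro), ("mag", self.mag)):
            if arr is None:
                continue
            if arr.shape != (n, 3):
                raise FormatError(
                    f"{name} must have shape ({n}, 3), got {arr.shape}"
                )
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise FormatError("t must be strictly increasing")
            nominal = 1.0 / self.meta.sample_rate_hz
            med = float(np.median(dt))
            if abs(med - nominal) > TIMING_JITTER_TOL * nominal:
                raise ConsistencyError(
                    f"median sample interval {med:.6g}s deviates more than "
                    f"{TIMING_JITTER_TOL:.0%} from nominal {nominal:.6g}s"
                )

    # -- convenience -----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return int(self.t.shape[0])

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        if self.n_samples < 3:
            return True
        dt = np.diff(self.t)
        return bool(np.ptp(dt) <= rtol * np.median(dt))

    def axis(self, stream: str, axis: str) -> np.ndarray:
        """One channel by stream name ('accel'|'gyro'|'mag') and device axis."""
        arr = getattr(self, stream)
        if arr is None:
            raise FormatError(f"recording has no {stream} stream")
        return arr[:, AxisConvention.index(axis)]

    def equals(self, other: "InertialRecording", atol: float = 1e-9) -> bool:
        if self.meta != other.meta:
            return False
        if (self.mag is None) != (other.mag is None):
            return False
        pairs = [(self.t, other.t), (self.accel, other.accel), (self.gyro, other.gyro)]
        if self.mag is not None:
            pairs.append((self.mag, other.mag))
        return all(
            a.shape == b.shape and np.allclose(a, b, rtol=0.0, atol=atol)
            for a, b in pairs
        )


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_recording(path: "str | Path") -> InertialRecording:
    """Read a recording CSV plus its JSON sidecar.

    The sidecar's ``accel_unit`` ('m/s^2' or 'g') and ``gyro_unit`` ('rad/s'
    or 'deg/s') declare the CSV units; channels are converted to the canonical
    m/s^2 and rad/s on read. The declared ``sample_rate_hz`` must agree with
    the observed median sample interval within 5%.
    """
    path = Path(path)
    side = _sidecar_path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not side.exists():
        raise FormatError(f"missing metadata sidecar {side}")
    try:
        raw_meta = json.loads(side.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"sidecar {side} is not valid JSON: {exc}") from exc

    for key in ("user_id", "trial_type", "started_at", "sample_rate_hz"):
        if key not in raw_meta:
            raise FormatError(f"sidecar {side} lacks required key {key!r}")

    accel_unit = raw_meta.get("accel_unit", "m/s^2")
    gyro_unit = raw_meta.get("gyro_unit", "rad/s")
    if accel_unit not in _ACCEL_UNIT_FACTORS:
        raise FormatError(f"unknown accel_unit {accel_unit!r}")
    if gyro_unit not in _GYRO_UNIT_FACTORS:
        raise FormatError(f"unknown gyro_unit {gyro_unit!r}")

    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"recording CSV lacks column(s): {', '.join(missing)}")
    has_mag = all(c in df.columns for c in _MAG_COLUMNS)
    for col in _CSV_COLUMNS + (_MAG_COLUMNS if has_mag else []):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"column {col!r} is not numeric")

    try:
        meta = RecordingMetadata(
            user_id=str(raw_meta["user_id"]),
            trial_type=TrialType(raw_meta["trial_type"]),
            started_at=str(raw_meta["started_at"]),
            sample_rate_hz=float(raw_meta["sample_rate_hz"]),
            device_label=str(raw_meta.get("device_label", "")),
        )
    except ValueError as exc:
        raise FormatError(f"bad metadata in {side}: {exc}") from exc

    t = df["t"].to_numpy(dtype=float)
    accel = df[["ax", "ay", "az"]].to_numpy(dtype=float) * _ACCEL_UNIT_FACTORS[accel_unit]
    gyro = df[["gx", "gy", "gz"]].to_numpy(dtype=float) * _GYRO_UNIT_FACTORS[gyro_unit]
    mag = df[_MAG_COLUMNS].to_numpy(dtype=float) if has_mag else None

    try:
        return InertialRecording(t=t, accel=accel, gyro=gyro, mag=mag, meta=meta)
    except ConsistencyError as exc:
        raise ConsistencyError(f"{path}: {exc}") from exc


def write_recording(rec: InertialRecording, path: "str | Path") -> None:
    """Write ``rec`` as CSV + JSON sidecar in canonical units.

    Round-trips through :func:`read_recording` with exact metadata equality
    and numeric drift below 1e-9 (12 significant digits are written).
    """
    rec.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    cols = {"t": rec.t}
    for prefix, arr in (("a", rec.accel), ("g", rec.gyro)):
        for i, ax in enumerate("xyz"):
            cols[f"{prefix}{ax}"] = arr[:, i]
    if rec.mag is not None:
        for i, ax in enumerate("xyz"):
            cols[f"m{ax}"] = rec.mag[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")

    meta = {
        "user_id": rec.meta.user_id,
        "trial_type": rec.meta.trial_type.value,
        "started_at": rec.meta.started_at,
        "sample_rate_hz": rec.meta.sample_rate_hz,
        "device_label": rec.meta.device_label,
        "accel_unit": "m/s^2",
        "gyro_unit": "rad/s",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Conditioning
# ---------------------------------------------------------------------------

def resample_uniform(rec: InertialRecording, fs: Optional[float] = None) -> InertialRecording:
    """Linearly resample a recording onto an exactly uniform time grid.

    Consumer-phone sensor timestamps jitter; downstream filters assume a
    uniform rate. The output grid spans ``[t[0], t[-1]]`` at interval
    ``1/fs`` (default: the metadata's nominal rate), re-zeroed to start at 0.
    Idempotent on already-uniform input (returns values identical to 1e-9).
    """
    if rec.n_samples < 2:
        raise InsufficientDataError("resampling requires at least 2 samples")
    if fs is None:
        fs = rec.meta.sample_rate_hz
    if not fs > 0:
        raise ConfigError(f"fs must be > 0, got {fs}")

    t_old = rec.t - rec.t[0]
    span = t_old[-1]
    n_new = int(math.floor(span * fs + 1e-9)) + 1
    t_new = np.arange(n_new) / fs

    def interp(arr: Optional[np.ndarray]) -> Optional[np.ndarray]:
        if arr is None:
            return None
        return np.column_stack([np.interp(t_new, t_old, arr[:, i]) for i in range(3)])

    meta = replace(rec.meta, sample_rate_hz=float(fs))
    return InertialRecording(
        t=t_new,
        accel=interp(rec.accel),
        gyro=interp(rec.gyro),
        mag=interp(rec.mag),
        meta=meta,
    )
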