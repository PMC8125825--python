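"""Reading and writing recordings, segment annotations and calibration files.

Recordings are wide CSVs with one row per synchronized sample: a time column
``t_s`` followed by triaxial gyroscope columns ``<placement>_g{x,y,z}`` for the
six placements (left/right wrist, thumb and index: LW, LT, LI, RW, RT, RI) in
degrees per second, and optional accelerometer columns ``<placement>_a{x,y,z}``
in g.  All sensors are sampled on a common clock, so no per-sensor delay column
exists.

Segment annotations are CSVs with one row per activity repetition giving the
participant, activity name, repetition index, the half-open time window
``[t_start_s, t_end_s)`` and the experimenter-assigned true category.

Calibration files map each (sensor, axis) to a linear gain/offset pair that
converts raw integer counts into physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .categories import Category
from .errors import (
    DataError,
    FormatError,
    LookupError_,
    SingularFitError,
)

PLACEMENTS: Tuple[str, ...] = ("LW", "LT", "LI", "RW", "RT", "RI")
AXES: Tuple[str, ...] = ("x", "y", "z")

LEFT_PLACEMENTS = ("LW", "LT", "LI")
RIGHT_PLACEMENTS = ("RW", "RT", "RI")
WRIST = {"left": "LW", "right": "RW"}
FINGERS = {"left": ("LT", "LI"), "right": ("RT", "RI")}

#: Relative tolerance used to validate timestamps against the declared rate.
TIME_RTOL = 1e-6

#: Default maximum repetition duration in seconds.
MAX_SEGMENT_DURATION_S = 25.0


def gyro_columns() -> List[str]:
    return [f"{p}_g{a}" for p in PLACEMENTS for a in AXES]


def accel_columns() -> List[str]:
    return [f"{p}_a{a}" for p in PLACEMENTS for a in AXES]


@dataclass
class Recording:
    """One participant session: synchronized six-sensor gyroscope series.

    Parameters
    ----------
    participant_id
        Identifier of the participant.
    sample_rate_hz
        Sampling rate shared by all sensors, > 0.
    t
        Timestamps in seconds, strictly increasing, uniform at ``1/sample_rate_hz``.
    gyro
        Mapping placement -> ``(n, 3)`` array of angular velocity in deg/s.
    accel
        Optional mapping placement -> ``(n, 3)`` array of acceleration in g.
    """

    participant_id: str
    sample_rate_hz: float
    t: np.ndarray
    gyro: Dict[str, np.ndarray]
    accel: Optional[Dict[str, np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise DataError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        self.t = np.asarray(self.t, dtype=float)
        n = self.t.shape[0]
        missing = [p for p in PLACEMENTS if p not in self.gyro]
        if missing:
            raise DataError(f"missing gyroscope placements: {missing}")
        for p in PLACEMENTS:
            arr = np.asarray(self.gyro[p], dtype=float)
            if arr.shape != (n, 3):
                raise DataError(
                    f"gyro series {p} has shape {arr.shape}, expected ({n}, 3)"
                )
            if not np.all(np.isfinite(arr)):
                raise DataError(f"gyro series {p} contains NaN or infinite values")
            self.gyro[p] = arr
        if self.accel is not None:
            for p, arr in self.accel.items():
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (n, 3):
                    raise DataError(
                        f"accel series {p} has shape {arr.shape}, expected ({n}, 3)"
                    )
                self.accel[p] = arr
        if n == 0:
            raise DataError("recording has no samples")
        if not np.all(np.isfinite(self.t)):
            raise DataError("timestamps contain NaN or infinite values")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise DataError("timestamps are not strictly increasing")
            expected = 1.0 / self.sample_rate_hz
            if not np.allclose(dt, expected, rtol=TIME_RTOL, atol=expected * TIME_RTOL):
                raise DataError(
                    "timestamps are not uniform at the declared sample rate"
                )

    @property
    def n_samples(self) -> int:
        return int(self.t.shape[0])

    @property
    def duration_s(self) -> float:
        # duration counts the final sample's interval
        return self.n_samples / self.sample_rate_hz

    def to_frame(self) -> pd.DataFrame:
        data: Dict[str, np.ndarray] = {"t_s": self.t}
        for p in PLACEMENTS:
            for j, a in enumerate(AXES):
                data[f"{p}_g{a}"] = self.gyro[p][:, j]
        if self.accel is not None:
            for p in PLACEMENTS:
                if p in self.accel:
                    for j, a in enumerate(AXES):
                        data[f"{p}_a{a}"] = self.accel[p][:, j]
        return pd.DataFrame(data)


@dataclass
class ActivitySegment:
    """An annotated activity repetition inside one participant's recording.

    The time window is half-open: a sample at ``t_end_s`` is excluded, so
    consecutive windows concatenate without overlap.
    """

    participant_id: str
    activity: str
    repetition: int
    t_start_s: float
    t_end_s: float
    true_category: Category
    performed_hand: str = "unknown"

    def __post_init__(self) -> None:
        self.true_category = Category.parse(self.true_category)
        if self.repetition < 1:
            raise DataError(f"repetition must be >= 1, got {self.repetition}")
        if not self.t_end_s > self.t_start_s:
            raise DataError(
                f"segment window invalid: t_end_s={self.t_end_s} <= "
                f"t_start_s={self.t_start_s}"
            )
        if self.performed_hand not in ("left", "right", "both", "unknown"):
            raise DataError(f"unknown performed_hand {self.performed_hand!r}")

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s


def read_recording(
    path: "str | Path",
    sample_rate_hz: float,
    participant_id: Optional[str] = None,
) -> Recording:
    """Read a wide-format recording CSV.

    ``participant_id`` defaults to the file stem.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["t_s"] + gyro_columns()
    for col in required:
        if col not in df.columns:
            raise FormatError(f"recording file {path.name} is missing column {col!r}")
    if df[required].isna().any().any():
        raise DataError(f"recording file {path.name} contains missing values")
    t = df["t_s"].to_numpy(dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise DataError(f"recording file {path.name} has non-monotone timestamps")
    gyro = {
        p: df[[f"{p}_g{a}" for a in AXES]].to_numpy(dtype=float) for p in PLACEMENTS
    }
    accel = None
    if all(c in df.columns for c in accel_columns()):
        accel = {
            p: df[[f"{p}_a{a}" for a in AXES]].to_numpy(dtype=float)
            for p in PLACEMENTS
        }
    return Recording(
        participant_id=participant_id or path.stem,
        sample_rate_hz=sample_rate_hz,
        t=t,
        gyro=gyro,
        accel=accel,
    )


def write_recording(recording: Recording, path: "str | Path") -> Path:
    """Write a recording in the wide CSV dialect; round-trips bit-identically."""
    path = Path(path)
    # shortest-unique repr so float64 values survive the CSV round trip exactly
    recording.to_frame().to_csv(
        path, index=False, float_format=lambda v: repr(float(v))
    )
    return path


SEGMENT_COLUMNS = [
    "participant_id",
    "activity",
    "repetition",
    "t_start_s",
    "t_end_s",
    "true_category",
    "performed_hand",
]


def read_segments(
    path: "str | Path",
    max_duration_s: float = MAX_SEGMENT_DURATION_S,
) -> List[ActivitySegment]:
    """Read a segment-annotation CSV, sorted by (participant, activity, repetition)."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in SEGMENT_COLUMNS:
        if col == "performed_hand" and col not in df.columns:
            df[col] = "unknown"
            continue
        if col not in df.columns:
            raise FormatError(f"segments file {path.name} is missing column {col!r}")
    segments = []
    for row in df.itertuples(index=False):
        try:
            category = Category.parse(row.true_category)
        except ValueError as exc:
            raise DataError(str(exc)) from exc
        seg = ActivitySegment(
            participant_id=str(row.participant_id),
            activity=str(row.activity),
            repetition=int(row.repetition),
            t_start_s=float(row.t_start_s),
            t_end_s=float(row.t_end_s),
            true_category=category,
            performed_hand=str(row.performed_hand),
        )
        if seg.duration_s > max_duration_s:
            raise DataError(
                f"segment {seg.participant_id}/{seg.activity} rep {seg.repetition} "
                f"lasts {seg.duration_s:.2f} s > {max_duration_s} s"
            )
        segments.append(seg)
    segments.sort(key=lambda s: (s.participant_id, s.activity, s.repetition))
    return segments


def write_segments(segments: Sequence[ActivitySegment], path: "str | Path") -> Path:
    path = Path(path)
    rows = [
        {
            "participant_id": s.participant_id,
            "activity": s.activity,
            "repetition": s.repetition,
            "t_start_s": s.t_start_s,
            "t_end_s": s.t_end_s,
            "true_category": s.true_category.value,
            "performed_hand": s.performed_hand,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Calibration


@dataclass(frozen=True)
class AxisCalibration:
    """Linear calibration for one sensor axis: value = (raw - offset) * gain."""

    gain: float
    offset: float

    def __post_init__(self) -> None:
        if self.gain == 0:
            raise DataError("calibration gain must be nonzero")


@dataclass
class CalibrationCoefficients:
    """Per-sensor, per-axis linear gain/offset pairs."""

    coeffs: Dict[Tuple[str, str], AxisCalibration] = field(default_factory=dict)

    def get(self, sensor: str, axis: str) -> AxisCalibration:
        try:
            return self.coeffs[(sensor, axis)]
        except KeyError:
            raise LookupError_(
                f"no calibration coefficients for sensor {sensor!r} axis {axis!r}"
            ) from None


def fit_axis_calibration(
    pairs: Sequence[Tuple[float, float]],
) -> AxisCalibration:
    """Least-squares fit of the linear model ``raw = value / gain + offset``.

    ``pairs`` are (reference_value, raw_counts) observations, e.g. holding the
    accelerometer at 0 g, +1 g and -1 g, or spinning the gyroscope at known
    reference speeds.  At least two distinct reference values are required.
    """
    values = np.asarray([p[0] for p in pairs], dtype=float)
    raws = np.asarray([p[1] for p in pairs], dtype=float)
    if np.unique(values).size < 2:
        raise SingularFitError(
            "calibration fit needs at least two distinct reference values"
        )
    # raw = a * value + b with a = 1/gain, b = offset
    a, b = np.polyfit(values, raws, deg=1)
    if a == 0:
        raise SingularFitError("calibration fit produced zero slope")
    return AxisCalibration(gain=1.0 / a, offset=b)


def fit_calibration(
    readings: Mapping[Tuple[str, str], Sequence[Tuple[float, float]]],
) -> CalibrationCoefficients:
    """Fit per-axis linear calibrations for every (sensor, axis) in ``readings``."""
    return CalibrationCoefficients(
        coeffs={key: fit_axis_calibration(pairs) for key, pairs in readings.items()}
    )


def apply_calibration(
    raw_series: np.ndarray,
    coeffs: "CalibrationCoefficients | AxisCalibration",
    sensor: Optional[str] = None,
    axis: Optional[str] = None,
) -> np.ndarray:
    """Convert raw counts to physical units: ``(raw - offset) * gain``.

    Pass either an :class:`AxisCalibration` directly, or a
    :class:`CalibrationCoefficients` plus ``sensor`` and ``axis`` to look up.
    """
    if isinstance(coeffs, CalibrationCoefficients):
        if sensor is None or axis is None:
            raise LookupError_("sensor and axis required to look up coefficients")
        coeffs = coeffs.get(sensor, axis)
    raw = np.asarray(raw_series, dtype=float)
    return (raw - coeffs.offset) * coeffs.gain


def read_calibration(path: "str | Path") -> CalibrationCoefficients:
    """Read a ``sensor,axis,gain,offset`` CSV."""
    df = pd.read_csv(path)
    for col in ("sensor", "axis", "gain", "offset"):
        if col not in df.columns:
            raise FormatError(f"calibration file is missing column {col!r}")
    coeffs = {
        (str(r.sensor), str(r.axis)): AxisCalibration(float(r.gain), float(r.offset))
        for r in df.itertuples(index=False)
    }
    return CalibrationCoefficients(coeffs=coeffs)


def write_calibration(
    calibration: CalibrationCoefficients, path: "str | Path"
) -> Path:
    rows = [
        {"sensor": s, "axis": a, "gain": c.gain, "offset": c.offset}
        for (s, a), c in sorted(calibration.coeffs.items())
    ]
    pd.DataFrame(rows, columns=["sensor", "axis", "gain", "offset"]).to_csv(
        path, index=False
    )
    return Path(path)
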