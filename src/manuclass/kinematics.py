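"""Scalar activity signals from triaxial gyroscope series.

The classifier never looks at individual axes: each sensor's triaxial angular
velocity is collapsed to its Euclidean norm (the angular speed), and segment
features are built from time-averages of those norms.  No filtering is applied
to the raw signals at any point.

Aggregates follow the sensor layout: the *hand signal* is the mean of the
three sensors on one hand (wrist, thumb, index) and the *fingers signal* is
the mean of the two finger sensors.  Segment means are computed per sensor
first and then averaged; with synchronized uniform sampling this equals
averaging the aggregate signal and then taking the segment mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from .errors import DataError, EmptySegmentError
from .io import FINGERS, PLACEMENTS, WRIST, ActivitySegment, Recording


def norm_series(gyro_xyz: np.ndarray) -> np.ndarray:
    """Elementwise Euclidean norm of a triaxial series.

    Accepts an ``(n, 3)`` array (or three equal-length rows as ``(3, n)``
    transposed by the caller) and returns the ``(n,)`` angular-speed series.
    """
    arr = np.asarray(gyro_xyz, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise DataError(f"expected an (n, 3) triaxial series, got shape {arr.shape}")
    return np.sqrt(np.einsum("ij,ij->i", arr, arr))


@dataclass
class MeanSpeeds:
    """Time-averaged angular speeds of one segment, at every aggregation level.

    All values are nonnegative and in deg/s.  ``hand[side]`` is the arithmetic
    mean of that side's three per-sensor means and ``fingers[side]`` the mean
    of its thumb and index means.
    """

    per_sensor: Dict[str, float]
    hand: Dict[str, float]
    fingers: Dict[str, float]
    wrist: Dict[str, float]


def segment_indices(recording: Recording, segment: ActivitySegment) -> np.ndarray:
    """Sample indices falling in the half-open window [t_start, t_end)."""
    if segment.t_start_s < recording.t[0] - 1e-12 or segment.t_end_s > (
        recording.t[-1] + 1.0 / recording.sample_rate_hz + 1e-12
    ):
        raise DataError(
            f"segment window [{segment.t_start_s}, {segment.t_end_s}) outside "
            f"recording span [{recording.t[0]}, {recording.duration_s})"
        )
    mask = (recording.t >= segment.t_start_s) & (recording.t < segment.t_end_s)
    return np.flatnonzero(mask)


def mean_speeds(recording: Recording, segment: ActivitySegment) -> MeanSpeeds:
    """Per-sensor, per-hand and per-fingers mean angular speeds over a segment.

    The per-sensor mean is the time-average of the norm series inside the
    window — not the norm of the time-averaged vector, which would cancel
    oscillatory motion.
    """
    idx = segment_indices(recording, segment)
    if idx.size == 0:
        raise EmptySegmentError(
            f"segment {segment.activity} rep {segment.repetition} of "
            f"{segment.participant_id} contains no samples"
        )
    per_sensor = {
        p: float(np.mean(norm_series(recording.gyro[p][idx]))) for p in PLACEMENTS
    }
    hand = {}
    fingers = {}
    wrist = {}
    for side in ("left", "right"):
        w = WRIST[side]
        f1, f2 = FINGERS[side]
        wrist[side] = per_sensor[w]
        fingers[side] = (per_sensor[f1] + per_sensor[f2]) / 2.0
        hand[side] = (per_sensor[w] + per_sensor[f1] + per_sensor[f2]) / 3.0
    return MeanSpeeds(per_sensor=per_sensor, hand=hand, fingers=fingers, wrist=wrist)
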