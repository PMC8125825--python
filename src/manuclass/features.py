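"""The two classification features: hands ratio and fingers-to-wrist ratio.

For each activity repetition:

* **HR (hands ratio)** — mean angular speed of the most active hand divided by
  that of the least active hand.  Near 1 when both hands work equally; large
  when one hand dominates (unimanual tasks or a stabilizing hand).

* **FWR (fingers-to-wrist ratio)** — mean angular speed of the finger sensors
  divided by that of the wrist sensor of the same hand.  Near 1 for whole-hand
  movement (the fingers ride along with the wrist); larger when the fingers
  move independently.

Two FWR variants are always computed, because the decision tree uses a
different one per branch: ``fwr_active`` is the FWR of the most active hand
(the label-free proxy for the mover in stabilizing-hand tasks) and
``fwr_mean`` averages the two hands' FWRs (for tasks where both hands work).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import pandas as pd

from .categories import Category
from .errors import DataError
from .io import ActivitySegment, Recording
from .kinematics import MeanSpeeds, mean_speeds

#: Denominators below this (deg/s) are treated as zero; the ratio becomes +inf,
#: which compares greater than any finite cutoff downstream.
EPSILON = 1e-9


def hands_ratio(mean_hand_a: float, mean_hand_b: float) -> float:
    """Most-active over least-active hand mean speed; >= 1 by construction."""
    if mean_hand_a < 0 or mean_hand_b < 0:
        raise DataError("hand mean speeds must be nonnegative")
    hi, lo = max(mean_hand_a, mean_hand_b), min(mean_hand_a, mean_hand_b)
    if lo < EPSILON:
        return math.inf
    return hi / lo


def fingers_wrist_ratio(fingers_mean: float, wrist_mean: float) -> float:
    """Fingers mean speed over wrist mean speed of one hand."""
    if fingers_mean < 0 or wrist_mean < 0:
        raise DataError("mean speeds must be nonnegative")
    if wrist_mean < EPSILON:
        return math.inf
    return fingers_mean / wrist_mean


@dataclass
class FeatureVector:
    """HR and the two FWR variants for one repetition, plus audit quantities."""

    hr: float
    fwr_active: float
    fwr_mean: float
    fwr_left: float
    fwr_right: float
    most_active_hand: str
    speeds: Optional[MeanSpeeds] = None


def extract_features(recording: Recording, segment: ActivitySegment) -> FeatureVector:
    """Compute the feature vector of one annotated repetition.

    The most active hand is the one with the larger hand-signal mean; an exact
    tie breaks toward the right hand so the result is deterministic.
    """
    speeds = mean_speeds(recording, segment)
    hr = hands_ratio(speeds.hand["left"], speeds.hand["right"])
    fwr = {
        side: fingers_wrist_ratio(speeds.fingers[side], speeds.wrist[side])
        for side in ("left", "right")
    }
    most_active = "left" if speeds.hand["left"] > speeds.hand["right"] else "right"
    return FeatureVector(
        hr=hr,
        fwr_active=fwr[most_active],
        fwr_mean=(fwr["left"] + fwr["right"]) / 2.0,
        fwr_left=fwr["left"],
        fwr_right=fwr["right"],
        most_active_hand=most_active,
        speeds=speeds,
    )


FEATURE_COLUMNS = [
    "participant_id",
    "activity",
    "repetition",
    "true_category",
    "hr",
    "fwr_active",
    "fwr_mean",
    "most_active_hand",
]


def extract_feature_table(
    recordings: Mapping[str, Recording],
    segments: Iterable[ActivitySegment],
) -> pd.DataFrame:
    """Run feature extraction for every segment and assemble the feature table.

    ``recordings`` maps participant ids to their recordings; every segment's
    participant must be present.
    """
    rows: List[Dict] = []
    for seg in segments:
        if seg.participant_id not in recordings:
            raise DataError(f"no recording for participant {seg.participant_id!r}")
        fv = extract_features(recordings[seg.participant_id], seg)
        rows.append(
            {
                "participant_id": seg.participant_id,
                "activity": seg.activity,
                "repetition": seg.repetition,
                "true_category": seg.true_category.value,
                "hr": fv.hr,
                "fwr_active": fv.fwr_active,
                "fwr_mean": fv.fwr_mean,
                "most_active_hand": fv.most_active_hand,
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns and c != "most_active_hand"]
    if missing:
        raise DataError(f"feature table is missing columns {missing}")
    df["true_category"] = [Category.parse(c).value for c in df["true_category"]]
    return df


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
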