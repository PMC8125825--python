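"""Published reference values for the held-out-participant worked example.

The validation study of this classifier reported, for one held-out
participant, the hands ratio (HR) and fingers-to-wrist ratio (FWR) of every
repetition of the 14 activities, together with the cutoffs learned with that
participant excluded from training (20.96, 4.67, 2.61, 2.26 — essentially
identical to the whole-sample cutoffs).  Those printed values are embedded
here so the evaluation machinery can be exercised end-to-end without the
study's raw signals.

One printed inconsistency is preserved as a single value: for "Writing a
sentence" repetition 4 the source lists HR 20.13 at step 1 but 27.54 at
step 2, although both are the same quantity; this table stores the step-1
value (20.13), under which all three criteria pass, matching the repetition
being counted correct.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .categories import Category
from .roc import CutoffSet

#: Cutoffs learned with the reference participant excluded.
REFERENCE_CUTOFFS = CutoffSet(
    hr_unimanual=20.96, hr_stabilizing=4.67, fwr_stab=2.61, fwr_both=2.26
)

#: Cutoffs learned on the whole six-participant sample (identical values).
WHOLE_SAMPLE_CUTOFFS = CutoffSet(
    hr_unimanual=20.96, hr_stabilizing=4.67, fwr_stab=2.61, fwr_both=2.26
)

REFERENCE_PARTICIPANT = "P3"

# activity -> (category, five HR values, five FWR values or None)
_TABLE = {
    "Brushing one's hair": (
        Category.UNIMANUAL,
        [32.11, 54.26, 66.41, 68.41, 83.61],
        None,
    ),
    "Using a spoon": (
        Category.UNIMANUAL,
        [56.73, 32.44, 41.81, 67.44, 59.21],
        None,
    ),
    "Drinking a cup of water": (
        Category.UNIMANUAL,
        [48.90, 58.22, 68.75, 68.21, 85.08],
        None,
    ),
    "Writing a sentence": (
        Category.BIMANUAL_STAB_FINGER,
        [27.72, 25.11, 26.97, 20.13, 29.52],
        [2.80, 2.72, 2.80, 2.83, 2.68],
    ),
    "Spreading butter on a slice of bread": (
        Category.BIMANUAL_STAB_GLOBAL,
        [7.63, 8.10, 11.44, 10.69, 16.35],
        [1.72, 1.62, 1.61, 1.61, 1.49],
    ),
    "Opening a can with a can opener": (
        Category.BIMANUAL_STAB_GLOBAL,
        [5.92, 8.52, 9.98, 11.93, 11.41],
        [2.29, 2.67, 2.01, 2.10, 2.10],
    ),
    "Typing on a computer keyboard": (
        Category.BIMANUAL_BOTH_FINGER,
        [3.21, 2.50, 2.75, 3.11, 2.91],
        [5.77, 5.58, 5.20, 5.29, 5.36],
    ),
    "Shuffling and dealing cards": (
        Category.BIMANUAL_BOTH_FINGER,
        [2.80, 2.44, 2.58, 2.59, 2.58],
        [2.97, 3.28, 2.93, 3.23, 3.24],
    ),
    "Peeling potatoes with a knife": (
        Category.BIMANUAL_BOTH_FINGER,
        [1.74, 1.97, 1.93, 1.98, 1.94],
        [2.80, 2.62, 2.90, 3.07, 3.02],
    ),
    "Buttoning a shirt": (
        Category.BIMANUAL_BOTH_FINGER,
        [2.20, 2.01, 2.42, 2.16, 2.67],
        [3.00, 3.13, 2.88, 3.27, 3.16],
    ),
    "Tying shoelaces": (
        Category.BIMANUAL_BOTH_FINGER,
        [2.71, 4.27, 2.42, 3.16, 2.61],
        [2.75, 2.64, 2.85, 2.60, 2.54],
    ),
    "Opening a screw-topped jar": (
        Category.BIMANUAL_BOTH_GLOBAL,
        [1.93, 1.77, 1.78, 2.15, 1.92],
        [2.02, 1.98, 2.18, 1.94, 2.43],
    ),
    "Lifting a full pan": (
        Category.BIMANUAL_BOTH_GLOBAL,
        [1.51, 1.52, 1.54, 1.50, 1.51],
        [1.70, 1.55, 1.56, 1.50, 1.49],
    ),
    "Wringing a towel": (
        Category.BIMANUAL_BOTH_GLOBAL,
        [2.29, 2.17, 2.15, 2.54, 2.38],
        [2.01, 1.72, 2.19, 1.87, 1.73],
    ),
}


def load_reference_features() -> pd.DataFrame:
    """The held-out participant's per-repetition features as a feature table.

    The single printed FWR of each repetition is stored in both ``fwr_active``
    and ``fwr_mean`` (only the variant matching the activity's branch is
    consumed by the evaluation); unimanual activities have no FWR (NaN).
    """
    rows = []
    for activity, (category, hrs, fwrs) in _TABLE.items():
        for i, hr in enumerate(hrs):
            fwr = np.nan if fwrs is None else fwrs[i]
            rows.append(
                {
                    "participant_id": REFERENCE_PARTICIPANT,
                    "activity": activity,
                    "repetition": i + 1,
                    "true_category": category.value,
                    "hr": hr,
                    "fwr_active": fwr,
                    "fwr_mean": fwr,
                    "most_active_hand": "right",
                }
            )
    return pd.DataFrame(rows)
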