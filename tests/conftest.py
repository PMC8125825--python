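import numpy as np
import pytest

import manuclass as mc
from manuclass.io import AXES, PLACEMENTS


def make_recording(
    norms: dict,
    n: int = 100,
    sample_rate_hz: float = 100.0,
    participant_id: str = "P1",
    rng: "np.random.Generator | None" = None,
):
    """Recording whose per-sensor norm series are exactly constant.

    ``norms`` maps placement -> constant angular speed; the vector is put on
    the x axis so the Euclidean norm equals the constant.
    """
    gyro = {}
    for p in PLACEMENTS:
        v = float(norms.get(p, 0.0))
        arr = np.zeros((n, 3))
        arr[:, 0] = v
        gyro[p] = arr
    return mc.Recording(
        participant_id=participant_id,
        sample_rate_hz=sample_rate_hz,
        t=np.arange(n) / sample_rate_hz,
        gyro=gyro,
    )


def make_segment(
    t_start=0.0,
    t_end=1.0,
    participant_id="P1",
    activity="toy",
    repetition=1,
    category=mc.Category.UNIMANUAL,
):
    return mc.ActivitySegment(
        participant_id=participant_id,
        activity=activity,
        repetition=repetition,
        t_start_s=t_start,
        t_end_s=t_end,
        true_category=category,
    )


@pytest.fixture(scope="session")
def well_sep_features():
    """Feature table extracted from a small well-separated synthetic dataset."""
    recs, segs = mc.simulate_dataset(3, 2, params=mc.well_separated(), seed=11)
    return mc.extract_feature_table(recs, segs)


@pytest.fixture(scope="session")
def reference_features():
    return mc.load_reference_features()
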