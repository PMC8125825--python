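"""ROC analysis and learning the decision-tree cutoffs.

A scalar score is turned into a binary classifier by the rule
``score > threshold -> positive``.  Sweeping the threshold over all candidate
values traces the receiver operating characteristic: sensitivity (true
positive rate) against 1 - specificity (false positive rate).  The working
cutoff is the threshold maximizing Youden's J = sensitivity + specificity - 1,
i.e. the point that jointly maximizes sensitivity and specificity and hence
minimizes misclassifications for balanced costs.

Four such analyses, on nested subsets of a labeled feature table, yield the
full cutoff set of the classifier:

* step 1 — HR on all repetitions, positive class = unimanual;
* step 2 — HR on bimanual repetitions, positive = stabilizing hand;
* step 3a — FWR of the active hand on stabilizing-hand repetitions,
  positive = finger activity;
* step 3b — mean FWR on both-hands repetitions, positive = finger activity.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .categories import Category
from .errors import DataError, DegenerateLabelsError


class RocPoint(NamedTuple):
    threshold: float
    sensitivity: float
    one_minus_specificity: float


def _candidate_thresholds(scores: np.ndarray, convention: str) -> np.ndarray:
    distinct = np.unique(scores)
    if convention == "midpoint":
        inner = (distinct[:-1] + distinct[1:]) / 2.0
    elif convention == "observed-value":
        inner = distinct
    else:
        raise ValueError(f"unknown threshold convention {convention!r}")
    return np.concatenate(([-np.inf], inner, [np.inf]))


def roc_curve(
    scores: Sequence[float],
    labels: Sequence[int],
    convention: str = "midpoint",
) -> List[RocPoint]:
    """ROC points for the rule ``score > threshold -> positive``.

    Candidate thresholds are midpoints between adjacent distinct scores
    (default) or the observed score values, plus -inf/+inf sentinels.  Rates
    are computed by exact counting, so the curve is correct for tied scores.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise DataError("scores and labels must have equal length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("both classes must be present for a ROC curve")
    points = []
    for thr in _candidate_thresholds(s, convention):
        pred = s > thr
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        points.append(RocPoint(float(thr), tp / n_pos, fp / n_neg))
    return points


def auc(roc: Sequence[RocPoint]) -> float:
    """Trapezoidal area under the ROC curve.

    Equals the Mann-Whitney probability that a random positive outscores a
    random negative, counting ties as 1/2.
    """
    fpr = np.asarray([p.one_minus_specificity for p in roc])
    tpr = np.asarray([p.sensitivity for p in roc])
    order = np.lexsort((tpr, fpr))
    return float(np.trapezoid(tpr[order], fpr[order]))


def optimal_cutoff(roc: Sequence[RocPoint]) -> float:
    """Threshold maximizing Youden's J; ties break toward the larger threshold.

    When the scores carry no information (e.g. all equal), no finite threshold
    beats the sentinels and the +inf sentinel is returned with a warning.
    """
    best_thr = -math.inf
    best_j = -math.inf
    for p in roc:
        j = p.sensitivity + (1.0 - p.one_minus_specificity)
        if j > best_j or (j == best_j and p.threshold > best_thr):
            best_j = j
            best_thr = p.threshold
    if not math.isfinite(best_thr):
        warnings.warn(
            "degenerate ROC: no finite threshold improves on the sentinels",
            stacklevel=2,
        )
    return best_thr


@dataclass
class CutoffSet:
    """The four learned thresholds of the three-step classifier.

    ``hr_unimanual`` separates uni- from bimanual repetitions (step 1);
    ``hr_stabilizing`` separates stabilizing-hand from both-hands bimanual
    ones (step 2) and is smaller than ``hr_unimanual`` because a stabilizing
    hand still moves a little; ``fwr_stab`` and ``fwr_both`` detect finger
    activity within each bimanual branch (step 3).
    """

    hr_unimanual: float
    hr_stabilizing: float
    fwr_stab: float
    fwr_both: float
    auc: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        for name in ("hr_unimanual", "hr_stabilizing", "fwr_stab", "fwr_both"):
            if getattr(self, name) <= 0:
                raise DataError(f"cutoff {name} must be > 0")

    def to_dict(self) -> Dict:
        d = {
            "hr_unimanual": self.hr_unimanual,
            "hr_stabilizing": self.hr_stabilizing,
            "fwr_stab": self.fwr_stab,
            "fwr_both": self.fwr_both,
        }
        if self.auc is not None:
            d["auc"] = dict(self.auc)
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "CutoffSet":
        return cls(
            hr_unimanual=float(d["hr_unimanual"]),
            hr_stabilizing=float(d["hr_stabilizing"]),
            fwr_stab=float(d["fwr_stab"]),
            fwr_both=float(d["fwr_both"]),
            auc=d.get("auc"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CutoffSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# (branch name, score column, subset predicate, positive predicate)
_BRANCHES = (
    ("hr_unimanual", "hr", lambda c: True, lambda c: c is Category.UNIMANUAL),
    (
        "hr_stabilizing",
        "hr",
        lambda c: c.is_bimanual,
        lambda c: c.is_stabilizing,
    ),
    (
        "fwr_stab",
        "fwr_active",
        lambda c: c.is_stabilizing,
        lambda c: c.is_finger,
    ),
    (
        "fwr_both",
        "fwr_mean",
        lambda c: c.is_bimanual and not c.is_stabilizing,
        lambda c: c.is_finger,
    ),
)


def branch_score_gaps(features: pd.DataFrame) -> Dict[str, Tuple[float, float]]:
    """Empirical between-class score gaps, one per learned cutoff.

    For each of the four ROC branches, returns (max score of the lower class,
    min score of the upper class) over the given feature table.  When the
    classes separate, a midpoint-convention cutoff learned from the same data
    lies strictly inside this interval.
    """
    cats = [Category.parse(c) for c in features["true_category"]]
    gaps: Dict[str, Tuple[float, float]] = {}
    for name, column, subset, positive in _BRANCHES:
        scores = features[column].to_numpy(dtype=float)
        neg = [s for s, c in zip(scores, cats) if subset(c) and not positive(c)]
        pos = [s for s, c in zip(scores, cats) if subset(c) and positive(c)]
        if not neg or not pos:
            raise DegenerateLabelsError(f"branch {name!r} is missing a class")
        gaps[name] = (max(neg), min(pos))
    return gaps


def learn_cutoffs(
    features: pd.DataFrame,
    convention: str = "midpoint",
) -> CutoffSet:
    """Learn the four cutoffs (and their AUCs) from a labeled feature table.

    The table needs columns ``true_category``, ``hr``, ``fwr_active`` and
    ``fwr_mean``; each of the four nested ROC analyses requires both of its
    classes to be present.
    """
    cats = [Category.parse(c) for c in features["true_category"]]
    results: Dict[str, float] = {}
    aucs: Dict[str, float] = {}
    for name, column, subset, positive in _BRANCHES:
        mask = np.asarray([subset(c) for c in cats])
        if not mask.any():
            raise DegenerateLabelsError(f"no repetitions available for ROC {name!r}")
        scores = features.loc[mask, column].to_numpy(dtype=float)
        labels = np.asarray([int(positive(c)) for c, m in zip(cats, mask) if m])
        if labels.min() == labels.max():
            raise DegenerateLabelsError(
                f"ROC {name!r} has a single class in its subset"
            )
        curve = roc_curve(scores, labels, convention=convention)
        results[name] = optimal_cutoff(curve)
        aucs[name] = auc(curve)
    return CutoffSet(
        hr_unimanual=results["hr_unimanual"],
        hr_stabilizing=results["hr_stabilizing"],
        fwr_stab=results["fwr_stab"],
        fwr_both=results["fwr_both"],
        auc=aucs,
    )
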