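"""The three-step decision tree, its evaluation, and leave-one-subject-out CV.

Classification proceeds in three steps over the two features:

1. ``hr > hr_unimanual`` → unimanual (stop); one hand is over twenty times
   more active than the other.
2. ``hr > hr_stabilizing`` → stabilizing-hand branch, else both-hands branch.
3. within the stabilizing branch, ``fwr_active > fwr_stab`` → finger
   activity; within the both-hands branch, ``fwr_mean > fwr_both`` → finger
   activity.  Otherwise the movement is a global (whole-hand) one.

All comparisons are strict; equality falls to the lower branch.

Evaluation mirrors the published green/red accounting: each repetition is
checked against the inequalities its *true* category must satisfy at every
applicable step, and it counts as correct only if all of them hold.  For
repetitions that would be routed down a wrong branch this differs from simply
comparing ``classify()`` output to the truth, so a conventional confusion
matrix is also reported as a supplementary view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .categories import CATEGORIES, Category
from .errors import DataError, DegenerateFoldError, DegenerateLabelsError
from .features import FeatureVector
from .roc import CutoffSet, learn_cutoffs


def classify(
    fv: Union[FeatureVector, "pd.Series"],
    cutoffs: CutoffSet,
) -> Category:
    """Assign a category to one repetition's feature vector."""
    hr = float(fv.hr if isinstance(fv, FeatureVector) else fv["hr"])
    fwr_active = float(
        fv.fwr_active if isinstance(fv, FeatureVector) else fv["fwr_active"]
    )
    fwr_mean = float(fv.fwr_mean if isinstance(fv, FeatureVector) else fv["fwr_mean"])
    if hr > cutoffs.hr_unimanual:
        return Category.UNIMANUAL
    if hr > cutoffs.hr_stabilizing:
        if fwr_active > cutoffs.fwr_stab:
            return Category.BIMANUAL_STAB_FINGER
        return Category.BIMANUAL_STAB_GLOBAL
    if fwr_mean > cutoffs.fwr_both:
        return Category.BIMANUAL_BOTH_FINGER
    return Category.BIMANUAL_BOTH_GLOBAL


def classify_table(features: pd.DataFrame, cutoffs: CutoffSet) -> pd.Series:
    """Vector version of :func:`classify` over a feature table."""
    return pd.Series(
        [classify(row, cutoffs).value for _, row in features.iterrows()],
        index=features.index,
        name="predicted_category",
    )


def criterion_checks(
    row: Union[FeatureVector, "pd.Series"],
    true_category: Category,
    cutoffs: CutoffSet,
) -> Dict[str, Optional[bool]]:
    """Pass/fail of the true category's expected inequality at each step.

    Steps that do not apply to the category (steps 2-3 for unimanual
    repetitions) are ``None``.
    """
    hr = float(row.hr if isinstance(row, FeatureVector) else row["hr"])
    fwr_active = float(
        row.fwr_active if isinstance(row, FeatureVector) else row["fwr_active"]
    )
    fwr_mean = float(
        row.fwr_mean if isinstance(row, FeatureVector) else row["fwr_mean"]
    )
    c = cutoffs
    if true_category is Category.UNIMANUAL:
        return {"step1": hr > c.hr_unimanual, "step2": None, "step3": None}
    checks: Dict[str, Optional[bool]] = {"step1": hr <= c.hr_unimanual}
    if true_category.is_stabilizing:
        checks["step2"] = hr > c.hr_stabilizing
        fwr = fwr_active
        cut = c.fwr_stab
    else:
        checks["step2"] = hr <= c.hr_stabilizing
        fwr = fwr_mean
        cut = c.fwr_both
    checks["step3"] = fwr > cut if true_category.is_finger else fwr <= cut
    return checks


@dataclass
class EvaluationReport:
    """Per-repetition criterion outcomes plus the accuracy tables built from them.

    ``per_repetition`` has one row per repetition with ``step{1,2,3}_pass``
    (nullable booleans), ``overall_correct`` and ``predicted_category``.
    ``activity_table`` and ``category_table`` give step-wise and overall
    accuracies as fractions in [0, 1]; repetitions are pooled, not averaged
    per activity.  ``confusion`` is the 5x5 matrix of true vs predicted
    categories from the routing view.
    """

    per_repetition: pd.DataFrame
    activity_table: pd.DataFrame
    category_table: pd.DataFrame
    confusion: pd.DataFrame
    overall_accuracy: float


_STEP_COLS = ("step1_pass", "step2_pass", "step3_pass")


def _accuracy_tables(per_rep: pd.DataFrame) -> "tuple[pd.DataFrame, pd.DataFrame, float]":
    def table(group_col: str) -> pd.DataFrame:
        rows = []
        for key, grp in per_rep.groupby(group_col, sort=True):
            row: Dict[str, object] = {group_col: key, "n": len(grp)}
            for i, col in enumerate(_STEP_COLS, start=1):
                vals = grp[col].dropna()
                row[f"step{i}_accuracy"] = (
                    float(vals.mean()) if len(vals) else np.nan
                )
            row["overall_accuracy"] = float(grp["overall_correct"].mean())
            rows.append(row)
        return pd.DataFrame(rows)

    overall = float(per_rep["overall_correct"].mean())
    return table("activity"), table("true_category"), overall


def evaluate(features: pd.DataFrame, cutoffs: CutoffSet) -> EvaluationReport:
    """Check every repetition against its true category's criteria.

    The feature table needs ``true_category``, ``hr``, ``fwr_active`` and
    ``fwr_mean`` columns (``activity`` is used for the per-activity table and
    defaults to the category when absent).
    """
    if features["true_category"].isna().any():
        raise DataError("every repetition needs a true category label")
    df = features.copy()
    if "activity" not in df.columns:
        df["activity"] = df["true_category"]
    records = []
    for _, row in df.iterrows():
        cat = Category.parse(row["true_category"])
        checks = criterion_checks(row, cat, cutoffs)
        applicable = [v for v in checks.values() if v is not None]
        records.append(
            {
                "participant_id": row.get("participant_id", ""),
                "activity": row["activity"],
                "repetition": row.get("repetition", np.nan),
                "true_category": cat.value,
                "hr": row["hr"],
                "fwr_active": row["fwr_active"],
                "fwr_mean": row["fwr_mean"],
                "step1_pass": checks["step1"],
                "step2_pass": checks["step2"],
                "step3_pass": checks["step3"],
                "overall_correct": all(applicable),
                "predicted_category": classify(row, cutoffs).value,
            }
        )
    per_rep = pd.DataFrame(records)
    for col in _STEP_COLS:
        per_rep[col] = per_rep[col].astype("boolean")
    activity_table, category_table, overall = _accuracy_tables(per_rep)
    labels = [c.value for c in CATEGORIES]
    confusion = (
        pd.crosstab(per_rep["true_category"], per_rep["predicted_category"])
        .reindex(index=labels, columns=labels, fill_value=0)
    )
    return EvaluationReport(
        per_repetition=per_rep,
        activity_table=activity_table,
        category_table=category_table,
        confusion=confusion,
        overall_accuracy=overall,
    )


@dataclass
class Fold:
    """One leave-one-subject-out iteration."""

    participant_id: str
    cutoffs: CutoffSet
    report: EvaluationReport


@dataclass
class CvResult:
    """All folds of a leave-one-subject-out run plus the pooled summary."""

    folds: List[Fold]
    summary: EvaluationReport


def loso_cv(features: pd.DataFrame, convention: str = "midpoint") -> CvResult:
    """Leave-one-subject-out cross-validation of the whole pipeline.

    For each participant: learn cutoffs from everyone else's repetitions,
    then evaluate the held-out participant against them.  Repetitions from
    all folds are pooled into the summary accuracy tables.
    """
    participants = sorted(features["participant_id"].astype(str).unique())
    if len(participants) < 2:
        raise DataError("leave-one-subject-out CV needs at least two participants")
    folds: List[Fold] = []
    for pid in participants:
        test_mask = features["participant_id"].astype(str) == pid
        train = features[~test_mask]
        try:
            cutoffs = learn_cutoffs(train, convention=convention)
        except DegenerateLabelsError as exc:
            raise DegenerateFoldError(
                f"training split excluding participant {pid!r} is degenerate: {exc}"
            ) from exc
        folds.append(Fold(pid, cutoffs, evaluate(features[test_mask], cutoffs)))
    pooled = pd.concat([f.report.per_repetition for f in folds], ignore_index=True)
    activity_table, category_table, overall = _accuracy_tables(pooled)
    labels = [c.value for c in CATEGORIES]
    confusion = (
        pd.crosstab(pooled["true_category"], pooled["predicted_category"])
        .reindex(index=labels, columns=labels, fill_value=0)
    )
    summary = EvaluationReport(
        per_repetition=pooled,
        activity_table=activity_table,
        category_table=category_table,
        confusion=confusion,
        overall_accuracy=overall,
    )
    return CvResult(folds=folds, summary=summary)
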