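"""Human-readable report rendering for cross-validation results.

Three files are produced per run: a per-repetition criterion grid (the
green/red accounting, as pass/fail flags), a step-wise accuracy table per
activity and per category, and a JSON summary with the per-fold cutoffs and
overall accuracy.  Rendering is pure: the same result renders byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from .classifier import CvResult, EvaluationReport
from .errors import DataError


def _percent(frac: object) -> str:
    if frac is None or pd.isna(frac):
        return "N/A"
    return f"{round(float(frac) * 100):.0f}%"


def _accuracy_csv(report: EvaluationReport) -> pd.DataFrame:
    """Step 1/2/3 and overall accuracy per activity and per category, as %."""
    frames = []
    for kind, table, key in (
        ("activity", report.activity_table, "activity"),
        ("category", report.category_table, "true_category"),
    ):
        df = table.copy()
        df.insert(0, "group_type", kind)
        df = df.rename(columns={key: "group"})
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    for col in ("step1_accuracy", "step2_accuracy", "step3_accuracy", "overall_accuracy"):
        out[col] = out[col].map(_percent)
    return out[
        [
            "group_type",
            "group",
            "n",
            "step1_accuracy",
            "step2_accuracy",
            "step3_accuracy",
            "overall_accuracy",
        ]
    ]


def render_report(
    cv: CvResult,
    out_dir: "str | Path",
    seed: Optional[int] = None,
) -> Dict[str, Path]:
    """Write the criterion grid, accuracy table and JSON summary for a CV run.

    Returns the paths written, keyed ``grid``, ``accuracy`` and ``summary``.
    """
    if not cv.folds:
        raise DataError("cannot render a report for a CvResult with no folds")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    grid_path = out_dir / "criterion_grid.csv"
    grid = cv.summary.per_repetition.copy()
    for col in ("step1_pass", "step2_pass", "step3_pass"):
        grid[col] = grid[col].map(
            lambda v: "N/A" if pd.isna(v) else ("pass" if v else "fail")
        )
    grid.to_csv(grid_path, index=False)

    accuracy_path = out_dir / "accuracy_table.csv"
    _accuracy_csv(cv.summary).to_csv(accuracy_path, index=False)

    summary_path = out_dir / "summary.json"
    summary = {
        "n_folds": len(cv.folds),
        "overall_accuracy": cv.summary.overall_accuracy,
        "folds": [
            {
                "held_out_participant": f.participant_id,
                "cutoffs": f.cutoffs.to_dict(),
                "overall_accuracy": f.report.overall_accuracy,
            }
            for f in cv.folds
        ],
    }
    if seed is not None:
        summary["seed"] = seed
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"grid": grid_path, "accuracy": accuracy_path, "summary": summary_path}
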