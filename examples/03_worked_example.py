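"""Re-run the published held-out-participant evaluation.

Feeds the published per-repetition HR/FWR values of one held-out participant
through the criterion evaluation with the cutoffs learned when that
participant was excluded, and prints the per-activity accuracies plus the
repetitions that fail a criterion (the "red cells").
"""

from manuclass import REFERENCE_CUTOFFS, evaluate, load_reference_features

features = load_reference_features()
report = evaluate(features, REFERENCE_CUTOFFS)

print("cutoffs:", REFERENCE_CUTOFFS.to_dict())
print(f"\noverall accuracy: {100 * report.overall_accuracy:.1f}%\n")
print("per-activity overall accuracy:")
for _, row in report.activity_table.iterrows():
    print(f"  {row['activity']:<40s} {100 * row['overall_accuracy']:.0f}%")

failures = report.per_repetition.query("~overall_correct")
print(f"\n{len(failures)} repetitions fail at least one criterion:")
for _, row in failures.iterrows():
    print(
        f"  {row['activity']:<40s} rep {int(row['repetition'])} "
        f"(hr={row['hr']:.2f}, fwr={row['fwr_mean']:.2f})"
    )
# "Using a spoon" and "Lifting a full pan" are 100% (5/5); the jar's fifth
# repetition (FWR 2.43 > 2.26) and the can opener's second (FWR 2.67 > 2.61)
# fail step 3, and four writing repetitions cross the step-1 HR cutoff --
# writing is the known borderline activity.
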