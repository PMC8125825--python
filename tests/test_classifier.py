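"""Three-step decision tree, green/red evaluation and LOSO cross-validation."""

import math

import numpy as np
import pandas as pd
import pytest

import manuclass as mc
from manuclass.errors import DataError, DegenerateFoldError
from manuclass.features import FeatureVector

CUTS = mc.REFERENCE_CUTOFFS  # (20.96, 4.67, 2.61, 2.26)


def fv(hr, fwr_active=1.0, fwr_mean=1.0):
    return FeatureVector(
        hr=hr, fwr_active=fwr_active, fwr_mean=fwr_mean,
        fwr_left=fwr_mean, fwr_right=fwr_mean, most_active_hand="right",
    )


class TestClassify:
    @pytest.mark.parametrize(
        "hr, fwr_active, fwr_mean, expected",
        [
            # published per-repetition values
            (56.73, 1.0, 1.0, "unimanual"),          # spoon rep 1
            (27.72, 2.80, 2.80, "unimanual"),        # writing rep 1, borderline
            (1.51, 1.70, 1.70, "bimanual_both_global"),   # full pan rep 1
            (2.80, 2.97, 2.97, "bimanual_both_finger"),   # cards rep 1
            # degenerate symmetric whole-hand motion
            (1.0, 1.0, 1.0, "bimanual_both_global"),
            # branch-by-branch
            (10.0, 3.0, 1.0, "bimanual_stab_finger"),
            (10.0, 2.0, 9.0, "bimanual_stab_global"),
            (math.inf, 1.0, 1.0, "unimanual"),
        ],
    )
    def test_tree_routing(self, hr, fwr_active, fwr_mean, expected):
        assert mc.classify(fv(hr, fwr_active, fwr_mean), CUTS).value == expected

    def test_equality_falls_to_lower_branch(self):
        assert mc.classify(fv(CUTS.hr_unimanual, 9.0, 9.0), CUTS) is not mc.Category.UNIMANUAL
        got = mc.classify(fv(CUTS.hr_stabilizing, 1.0, CUTS.fwr_both), CUTS)
        assert got is mc.Category.BIMANUAL_BOTH_GLOBAL

    def test_truth_table_on_exhaustive_grid(self):
        """classify agrees with a hand-written truth table over an (hr, fwr) lattice."""
        hr_grid = [1.0, 2.0, 4.67, 4.8, 10.0, 20.96, 21.5, 60.0, math.inf]
        fwr_grid = [0.5, 1.0, 2.26, 2.3, 2.61, 2.7, 6.0, math.inf]
        for hr in hr_grid:
            for fa in fwr_grid:
                for fm in fwr_grid:
                    if hr > 20.96:
                        want = "unimanual"
                    elif hr > 4.67:
                        want = "bimanual_stab_finger" if fa > 2.61 else "bimanual_stab_global"
                    else:
                        want = "bimanual_both_finger" if fm > 2.26 else "bimanual_both_global"
                    assert mc.classify(fv(hr, fa, fm), CUTS).value == want

    def test_monotone_in_hr(self):
        """Raising hr with fwr fixed only moves the prediction up the tree."""
        order = {
            "bimanual_both_global": 0, "bimanual_both_finger": 0,
            "bimanual_stab_global": 1, "bimanual_stab_finger": 1,
            "unimanual": 2,
        }
        for fa in (1.0, 3.0):
            for fm in (1.0, 3.0):
                levels = [
                    order[mc.classify(fv(hr, fa, fm), CUTS).value]
                    for hr in np.linspace(1, 40, 200)
                ]
                assert all(a <= b for a, b in zip(levels, levels[1:]))


class TestEvaluate:
    def test_worked_example_spoon_and_pan(self, reference_features):
        report = mc.evaluate(reference_features, CUTS)
        table = report.activity_table.set_index("activity")
        assert table.loc["Using a spoon", "overall_accuracy"] == 1.0
        pan = table.loc["Lifting a full pan"]
        assert pan["step1_accuracy"] == 1.0
        assert pan["step2_accuracy"] == 1.0
        assert pan["step3_accuracy"] == 1.0
        assert pan["overall_accuracy"] == 1.0

    def test_worked_example_known_failures(self, reference_features):
        pr = mc.evaluate(reference_features, CUTS).per_repetition
        jar5 = pr[(pr.activity == "Opening a screw-topped jar") & (pr.repetition == 5)]
        assert not jar5["step3_pass"].item()  # FWR 2.43 > 2.26
        can2 = pr[(pr.activity == "Opening a can with a can opener") & (pr.repetition == 2)]
        assert not can2["step3_pass"].item()  # FWR 2.67 > 2.61
        # and the writing repetitions with HR above the step-1 cutoff fail there
        writing = pr[pr.activity == "Writing a sentence"].set_index("repetition")
        assert not writing.loc[1, "step1_pass"]
        assert writing.loc[4, "step1_pass"]

    def test_all_correct_toy_table(self):
        df = pd.DataFrame(
            [
                {"activity": "a", "true_category": "unimanual",
                 "hr": 50.0, "fwr_active": 1.0, "fwr_mean": 1.0},
                {"activity": "b", "true_category": "bimanual_both_finger",
                 "hr": 2.0, "fwr_active": 3.0, "fwr_mean": 3.0},
            ]
        )
        report = mc.evaluate(df, CUTS)
        assert report.overall_accuracy == 1.0
        assert (report.activity_table["overall_accuracy"] == 1.0).all()

    def test_unimanual_steps_2_and_3_not_applicable(self, reference_features):
        pr = mc.evaluate(reference_features, CUTS).per_repetition
        uni = pr[pr.true_category == "unimanual"]
        assert uni["step2_pass"].isna().all()
        assert uni["step3_pass"].isna().all()

    def test_unlabeled_row_rejected(self):
        df = pd.DataFrame(
            [{"activity": "a", "true_category": None,
              "hr": 1.0, "fwr_active": 1.0, "fwr_mean": 1.0}]
        )
        with pytest.raises(DataError):
            mc.evaluate(df, CUTS)

    def test_criterion_view_agrees_with_routing_view(self, well_sep_features):
        """On non-borderline data, overall-correct equals classify == truth."""
        cutoffs = mc.learn_cutoffs(well_sep_features)
        report = mc.evaluate(well_sep_features, cutoffs)
        routing = report.per_repetition["predicted_category"] == report.per_repetition["true_category"]
        assert (report.per_repetition["overall_correct"] == routing).all()

    def test_confusion_matrix_diagonal_counts(self, well_sep_features):
        cutoffs = mc.learn_cutoffs(well_sep_features)
        report = mc.evaluate(well_sep_features, cutoffs)
        assert int(np.diag(report.confusion).sum()) == len(well_sep_features)


class TestLosoCv:
    def test_fold_count_and_partition(self, well_sep_features):
        cv = mc.loso_cv(well_sep_features)
        assert len(cv.folds) == well_sep_features["participant_id"].nunique()
        tested = cv.summary.per_repetition
        assert len(tested) == len(well_sep_features)
        key = ["participant_id", "activity", "repetition"]
        assert not tested.duplicated(subset=key).any()

    def test_identical_participants_give_identical_cutoffs(self):
        rng = np.random.default_rng(3)
        rows = []
        for cat, hr, fwr in [
            ("unimanual", 50, 1.5),
            ("bimanual_stab_finger", 10, 3.5),
            ("bimanual_stab_global", 10, 1.5),
            ("bimanual_both_finger", 2, 3.5),
            ("bimanual_both_global", 2, 1.5),
        ]:
            for rep in range(1, 4):
                jitter = rng.uniform(0.98, 1.02)
                for pid in ("A", "B"):
                    rows.append(
                        {"participant_id": pid, "activity": cat, "repetition": rep,
                         "true_category": cat, "hr": hr * jitter,
                         "fwr_active": fwr * jitter, "fwr_mean": fwr * jitter}
                    )
        cv = mc.loso_cv(pd.DataFrame(rows))
        assert len(cv.folds) == 2
        a, b = (f.cutoffs.to_dict() for f in cv.folds)
        assert a == b

    def test_single_participant_rejected(self, reference_features):
        with pytest.raises(DataError, match="two participants"):
            mc.loso_cv(reference_features)

    def test_degenerate_training_split_names_participant(self):
        # only participant B performs unimanual repetitions, so the fold that
        # holds B out trains on A alone and lacks that category
        rows = []
        for cat in [c.value for c in mc.CATEGORIES]:
            rows.append({"participant_id": "A", "activity": cat, "repetition": 1,
                         "true_category": cat, "hr": 2.0, "fwr_active": 1.5,
                         "fwr_mean": 1.5})
            rows.append({"participant_id": "B", "activity": cat, "repetition": 1,
                         "true_category": cat, "hr": 2.0, "fwr_active": 1.5,
                         "fwr_mean": 1.5})
        df = pd.DataFrame(rows)
        df.loc[(df.participant_id == "A") & (df.true_category == "unimanual"),
               "true_category"] = "bimanual_both_global"
        with pytest.raises(DegenerateFoldError, match="'B'"):
            mc.loso_cv(df)
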