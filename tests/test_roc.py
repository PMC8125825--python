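"""ROC construction, AUC and optimal-cutoff selection against brute-force oracles."""

import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import manuclass as mc
from manuclass.errors import DegenerateLabelsError


def sweep_oracle(scores, labels, thresholds):
    """Exhaustive counting of (sensitivity, 1-specificity) at each threshold."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    out = []
    for thr in thresholds:
        tp = fn = fp = tn = 0
        for s, y in zip(scores, labels):
            pred = s > thr
            if y == 1:
                tp += pred
                fn += not pred
            else:
                fp += pred
                tn += not pred
        out.append((tp / (tp + fn), fp / (fp + tn)))
    return out


def mann_whitney_oracle(scores, labels):
    """O(n^2) pairwise probability that a positive outscores a negative."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def random_instance(rng, n):
    labels = rng.integers(0, 2, size=n)
    while labels.min() == labels.max():
        labels = rng.integers(0, 2, size=n)
    # mixture with ties: half the scores drawn from a small integer grid
    scores = np.where(
        rng.random(n) < 0.5,
        rng.normal(labels.astype(float), 1.0),
        rng.integers(0, 5, size=n).astype(float),
    )
    return scores, labels


class TestRocCurve:
    def test_separable_has_perfect_point(self):
        curve = mc.roc_curve([1, 2, 3, 4], [0, 0, 1, 1])
        assert any(p.sensitivity == 1.0 and p.one_minus_specificity == 0.0 for p in curve)

    def test_interleaved_has_no_perfect_point(self):
        curve = mc.roc_curve([1, 2, 3, 4], [0, 1, 0, 1])
        assert not any(
            p.sensitivity == 1.0 and p.one_minus_specificity == 0.0 for p in curve
        )

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            mc.roc_curve([1, 2, 3], [1, 1, 1])

    def test_sensitivity_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        scores, labels = random_instance(rng, 60)
        curve = mc.roc_curve(scores, labels)
        sens = [p.sensitivity for p in sorted(curve, key=lambda p: p.threshold)]
        assert all(a >= b for a, b in zip(sens, sens[1:]))

    def test_counting_matches_oracle_on_many_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            scores, labels = random_instance(rng, int(rng.integers(6, 50)))
            curve = mc.roc_curve(scores, labels)
            oracle = sweep_oracle(scores, labels, [p.threshold for p in curve])
            for p, (sens, fpr) in zip(curve, oracle):
                assert p.sensitivity == sens
                assert p.one_minus_specificity == fpr


class TestAuc:
    def test_perfect_separation(self):
        assert mc.auc(mc.roc_curve([1, 2, 3, 4], [0, 0, 1, 1])) == pytest.approx(1.0)

    def test_identical_distributions(self):
        # positives and negatives share the same score multiset
        assert mc.auc(mc.roc_curve([1, 2, 1, 2], [0, 0, 1, 1])) == pytest.approx(0.5)

    def test_matches_mann_whitney_and_sklearn(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            scores, labels = random_instance(rng, int(rng.integers(6, 80)))
            a = mc.auc(mc.roc_curve(scores, labels))
            assert a == pytest.approx(mann_whitney_oracle(scores, labels), abs=1e-12)
            assert a == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        scores, labels = random_instance(rng, 50)
        a1 = mc.auc(mc.roc_curve(scores, labels))
        a2 = mc.auc(mc.roc_curve(np.exp(scores / 3.0), labels))
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestOptimalCutoff:
    def test_forced_by_separation(self):
        curve = mc.roc_curve([1, 2, 3, 4], [0, 0, 1, 1])
        assert mc.optimal_cutoff(curve) == pytest.approx(2.5)

    def test_degenerate_scores_warn_and_return_sentinel(self):
        curve = mc.roc_curve([3.0, 3.0, 3.0, 3.0], [0, 1, 0, 1])
        with pytest.warns(UserWarning, match="degenerate"):
            thr = mc.optimal_cutoff(curve)
        assert not math.isfinite(thr)

    def test_matches_brute_force_argmax(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            scores, labels = random_instance(rng, int(rng.integers(6, 100)))
            curve = mc.roc_curve(scores, labels)
            got = mc.optimal_cutoff(curve)
            oracle = sweep_oracle(scores, labels, [p.threshold for p in curve])
            js = [sens + (1 - fpr) for sens, fpr in oracle]
            best = max(js)
            candidates = [
                p.threshold for p, j in zip(curve, js) if j == best
            ]
            assert got == max(candidates)


class TestLearnCutoffs:
    def test_separated_synthetic_table(self):
        rng = np.random.default_rng(5)
        rows = []
        for cat, hr_lo, hr_hi in [
            ("unimanual", 45, 55),
            ("bimanual_stab_finger", 8, 12),
            ("bimanual_stab_global", 8, 12),
            ("bimanual_both_finger", 1.5, 2.5),
            ("bimanual_both_global", 1.5, 2.5),
        ]:
            finger = cat.endswith("finger")
            for _ in range(10):
                fwr = rng.uniform(3.0, 5.0) if finger else rng.uniform(1.0, 2.0)
                rows.append(
                    {"true_category": cat, "hr": rng.uniform(hr_lo, hr_hi),
                     "fwr_active": fwr, "fwr_mean": fwr}
                )
        import pandas as pd

        cutoffs = mc.learn_cutoffs(pd.DataFrame(rows))
        assert 15 < cutoffs.hr_unimanual < 45
        assert 2.5 < cutoffs.hr_stabilizing < 8
        assert 2.0 < cutoffs.fwr_stab < 3.0
        assert 2.0 < cutoffs.fwr_both < 3.0
        assert cutoffs.hr_unimanual > cutoffs.hr_stabilizing
        assert all(a == 1.0 for a in cutoffs.auc.values())

    def test_zero_training_misclassifications_when_separable(self, well_sep_features):
        cutoffs = mc.learn_cutoffs(well_sep_features)
        preds = mc.classify_table(well_sep_features, cutoffs)
        assert (preds == well_sep_features["true_category"]).all()

    def test_missing_branch_class_raises(self, well_sep_features):
        truncated = well_sep_features[
            well_sep_features["true_category"] != "bimanual_stab_finger"
        ]
        with pytest.raises(DegenerateLabelsError, match="fwr_stab"):
            mc.learn_cutoffs(truncated)

    def test_json_round_trip(self, tmp_path, well_sep_features):
        cutoffs = mc.learn_cutoffs(well_sep_features)
        path = tmp_path / "cutoffs.json"
        cutoffs.to_json(path)
        back = mc.CutoffSet.from_json(path)
        assert back.to_dict() == cutoffs.to_dict()
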