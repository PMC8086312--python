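"""Macro-F1 threshold calibration and the correct/mixed/none/other calls."""

import itertools

import numpy as np
import pandas as pd
import pytest

from oncopair.classify import ClassificationProfile, CVRepeat, CVResult
from oncopair.decision import (
    ThresholdConfig,
    assign_category,
    assign_subtype,
    macro_f1,
    optimize_threshold,
)
from _oracles import brute_category, brute_macro_f1


def profile_from(scores: np.ndarray, classes, samples=None) -> ClassificationProfile:
    samples = samples or [f"s{i}" for i in range(scores.shape[0])]
    return ClassificationProfile(pd.DataFrame(scores, index=samples, columns=classes))


def two_class_profile(score_a: list[float]) -> ClassificationProfile:
    arr = np.array([[v, 1 - v] for v in score_a])
    return profile_from(arr, ["A", "Unknown"])


class TestMacroF1:
    def test_perfect_classifier_scores_one(self):
        arr = np.eye(3)
        prof = profile_from(arr, ["A", "B", "Unknown"])
        truth = pd.Series(["A", "B", "Unknown"], index=prof.sample_ids)
        assert macro_f1(prof, truth, 0.5) == 1.0

    def test_harmonic_mean_hand_case(self):
        # class A: tp=12, fp=3, fn=8 -> precision .8, recall .6, F1 = 0.685714...
        score_a = [0.9] * 12 + [0.1] * 8 + [0.9] * 3 + [0.1] * 12
        truth = pd.Series(["A"] * 20 + ["Unknown"] * 15,
                          index=[f"s{i}" for i in range(35)])
        prof = two_class_profile(score_a)
        assert macro_f1(prof, truth, 0.5) == pytest.approx(2 * 0.8 * 0.6 / 1.4)

    def test_threshold_one_gives_zero(self):
        prof = two_class_profile([1.0, 0.0])
        truth = pd.Series(["A", "Unknown"], index=prof.sample_ids)
        assert macro_f1(prof, truth, 1.0) == 0.0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.dirichlet(np.ones(4), size=25)
        classes = ["A", "B", "C", "Unknown"]
        prof = profile_from(raw, classes)
        truth = pd.Series(rng.choice(classes, size=25), index=prof.sample_ids)
        for thr in rng.uniform(0, 1, size=5):
            assert macro_f1(prof, truth, float(thr)) == pytest.approx(
                brute_macro_f1(raw, classes, list(truth), float(thr))
            )

    def test_threshold_out_of_range_rejected(self):
        prof = two_class_profile([0.5])
        truth = pd.Series(["A"], index=prof.sample_ids)
        with pytest.raises(ValueError):
            macro_f1(prof, truth, 1.5)


def repeat_with_argmax(t_star: float) -> CVRepeat:
    """A repeat whose unique smallest macro-F1 maximizer is ``t_star``:
    one false positive at score t_star, one true positive at 0.9."""
    prof = two_class_profile([t_star, 0.9])
    truth = pd.Series(["Unknown", "A"], index=prof.sample_ids)
    return CVRepeat(profile=prof, truth=truth, train_samples=[],
                    holdout_samples=[], pair_names=[], seed=0)


class TestOptimizeThreshold:
    def test_mode_of_eligible_argmaxes(self):
        cv = CVResult(
            repeats=[repeat_with_argmax(t) for t in [0.25, 0.25, 0.31, 0.19, 0.25]],
            classes=["A", "Unknown"],
        )
        assert optimize_threshold(cv) == 0.25

    def test_below_floor_repeats_discarded_not_counted(self):
        cv = CVResult(
            repeats=[repeat_with_argmax(t) for t in [0.19, 0.19, 0.19, 0.31]],
            classes=["A", "Unknown"],
        )
        assert optimize_threshold(cv) == 0.31

    def test_single_repeat(self):
        cv = CVResult(repeats=[repeat_with_argmax(0.30)], classes=["A", "Unknown"])
        assert optimize_threshold(cv) == 0.30

    def test_mode_tie_breaks_to_smaller(self):
        cv = CVResult(
            repeats=[repeat_with_argmax(t) for t in [0.4, 0.4, 0.3, 0.3]],
            classes=["A", "Unknown"],
        )
        assert optimize_threshold(cv) == 0.3

    def test_all_below_floor_raises(self):
        cv = CVResult(repeats=[repeat_with_argmax(0.05)], classes=["A", "Unknown"])
        with pytest.raises(ValueError, match="floor"):
            optimize_threshold(cv)

    def test_grid_equals_exhaustive_enumeration(self):
        # per-repeat maximizer set recomputed by brute force over all 101 grid values
        rep = repeat_with_argmax(0.37)
        cfg = ThresholdConfig()
        grid = cfg.grid()
        assert len(grid) == 101
        vals = np.array([macro_f1(rep.profile, rep.truth, float(t)) for t in grid])
        best = grid[vals == vals.max()]
        assert best[0] == pytest.approx(0.37)
        cv = CVResult(repeats=[rep], classes=["A", "Unknown"])
        assert optimize_threshold(cv, cfg) == pytest.approx(best[0])

    def test_plateau_rule_on_near_perfect_scores(self):
        # perfect separation: F1 = 1 on a plateau starting below the floor;
        # the plateau rule still calibrates, the strict rule refuses
        prof = two_class_profile([0.05, 0.9])
        truth = pd.Series(["Unknown", "A"], index=prof.sample_ids)
        rep = CVRepeat(profile=prof, truth=truth, train_samples=[],
                       holdout_samples=[], pair_names=[], seed=0)
        cv = CVResult(repeats=[rep], classes=["A", "Unknown"])
        with pytest.raises(ValueError):
            optimize_threshold(cv, tie_rule="smallest")
        assert optimize_threshold(cv, tie_rule="plateau") == 0.21


class TestAssignCategory:
    CLASSES = ["OV", "UCEC", "LUAD", "Unknown"]

    def row(self, **scores):
        vals = {c: scores.get(c, 0.0) for c in self.CLASSES}
        rest = 1 - sum(vals.values())
        vals["Unknown"] += rest
        return pd.Series(vals, name="q1")

    def test_correct_call(self):
        row = self.row(OV=0.40, UCEC=0.20, LUAD=0.10)
        assert assign_category(row, "OV", 0.25).call == "correct"

    def test_mixed_call(self):
        row = self.row(OV=0.30, UCEC=0.45)
        assert assign_category(row, "OV", 0.25).call == "mixed"

    def test_other_and_none_calls(self):
        row = self.row(UCEC=0.45, OV=0.2, LUAD=0.2)   # only UCEC above threshold
        assert assign_category(row, "OV", 0.25).call == "other"
        row = self.row(OV=0.2, UCEC=0.2, LUAD=0.2)    # nothing above threshold
        assert assign_category(row, "OV", 0.25).call == "none"

    def test_unknown_top_forces_none(self):
        # a real class above threshold but Unknown holds the maximum
        row = self.row(OV=0.30)  # Unknown gets 0.70
        assert assign_category(row, "OV", 0.25).call == "none"

    def test_unknown_nominal_label_rejected(self):
        with pytest.raises(ValueError):
            assign_category(self.row(OV=0.5), "BRCA", 0.25)

    def test_truth_table_total_and_matches_verbal_rules(self):
        """Exhaustive check over every subset of above-threshold real classes
        and every nominal label for a 4-class profile."""
        real = ["OV", "UCEC", "LUAD", "BRCA"]
        classes = real + ["Unknown"]
        thr = 0.15
        for subset_size in range(len(real) + 1):
            for subset in itertools.combinations(real, subset_size):
                vals = {c: (0.2 if c in subset else 0.05) for c in real}
                vals["Unknown"] = 1 - sum(vals.values())
                row = pd.Series(vals, name="q")[classes]
                for nominal in real:
                    got = assign_category(row, nominal, thr)
                    expected = brute_category(dict(row), nominal, thr)
                    assert got.call == expected
                    assert got.call in {"correct", "mixed", "none", "other"}
                    assert set(got.classes_above_threshold) == set(subset)

    def test_raising_threshold_never_turns_none_into_correct(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            raw = rng.dirichlet(np.ones(5))
            row = pd.Series(raw, index=["A", "B", "C", "D", "Unknown"], name="q")
            t1, t2 = sorted(rng.uniform(0, 1, size=2))
            c1 = assign_category(row, "A", t1).call
            c2 = assign_category(row, "A", t2).call
            assert not (c1 == "none" and c2 == "correct")


class TestAssignSubtype:
    def row(self, **scores):
        idx = ["serous", "endometrioid", "clear_cell", "Unknown"]
        vals = {c: scores.get(c, 0.0) for c in idx}
        vals["Unknown"] += 1 - sum(vals.values())
        return pd.Series(vals, name="q")

    def test_single_subtype(self):
        assert assign_subtype(self.row(serous=0.6, endometrioid=0.1), 0.25) == ["serous"]

    def test_multiple_subtypes_is_mixed_call(self):
        got = assign_subtype(
            self.row(serous=0.3, endometrioid=0.3, clear_cell=0.25), 0.25)
        assert sorted(got) == ["endometrioid", "serous"]

    def test_unknown_when_top_is_unknown(self):
        assert assign_subtype(self.row(serous=0.3), 0.25) == "Unknown"  # Unknown .7

    def test_unknown_when_nothing_above(self):
        assert assign_subtype(self.row(serous=0.1, endometrioid=0.2), 0.25) == "Unknown"
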