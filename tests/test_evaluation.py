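"""Agreement metrics: Dice, ICC against a hand ANOVA, binomial CIs,
narrowest-slice comparison and report assembly."""

import numpy as np
import pandas as pd
import pytest

from canalseg import (
    ConfusionCounts,
    confusion_metrics,
    dice,
    evaluate_testset,
    icc,
    narrowest_slice_comparison,
)

TOY_TABLE = np.array([
    [118.0, 122.0],
    [96.0, 91.0],
    [73.0, 78.0],
    [140.0, 133.0],
    [105.0, 110.0],
    [62.0, 60.0],
])


def icc21_oracle(pairs: np.ndarray) -> float:
    """Independent mean-squares computation of ICC(2,1)."""
    n, k = pairs.shape
    grand = pairs.mean()
    row_means = pairs.mean(axis=1)
    col_means = pairs.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((pairs - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestDice:
    def test_identical_masks(self):
        m = np.random.default_rng(0).random((16, 16)) > 0.5
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[:4] = True
        b[4:] = True
        assert dice(a, b) == 0.0

    def test_constructed_half_overlap(self):
        """|A| = |B| = 100, |A & B| = 50 -> 2*50/200 = 0.5."""
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a.ravel()[:100] = True
        b.ravel()[50:150] = True
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_convention(self):
        assert dice(np.zeros((4, 4)), np.zeros((4, 4))) == 1.0

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = rng.random((12, 12)) > 0.6
            b = rng.random((12, 12)) > 0.6
            d = dice(a, b)
            assert d == dice(b, a)
            assert 0.0 <= d <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((4, 4)), np.zeros((5, 5)))


class TestICC:
    def test_identical_raters_equal_one(self):
        pairs = np.column_stack([TOY_TABLE[:, 0], TOY_TABLE[:, 0]])
        est, _ = icc(pairs)
        assert est == pytest.approx(1.0, abs=1e-9)

    def test_matches_hand_anova_to_1e6(self):
        est, (lo, hi) = icc(TOY_TABLE)
        assert est == pytest.approx(icc21_oracle(TOY_TABLE), abs=1e-6)
        assert lo <= est <= hi

    def test_constant_offset_lowers_absolute_agreement(self):
        shifted = TOY_TABLE.copy()
        shifted[:, 1] += 25.0
        est_base, _ = icc(TOY_TABLE)
        est_shift, _ = icc(shifted)
        assert est_shift < est_base
        assert est_shift == pytest.approx(icc21_oracle(shifted), abs=1e-6)

    def test_zero_variance_signalled(self):
        with pytest.raises(ValueError, match="variance"):
            icc(np.full((5, 2), 7.0))

    def test_bounded_above_by_one(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            pairs = rng.normal(100, 20, size=(10, 1))
            pairs = np.column_stack([pairs[:, 0], pairs[:, 0] + rng.normal(0, 5, 10)])
            est, _ = icc(pairs)
            assert est <= 1.0 + 1e-12


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=30, fp=0, tn=70, fn=0))
        for name in ("accuracy", "sensitivity", "specificity"):
            assert m[name]["percent"] == 100.0

    def test_zero_denominator_is_nan_not_error(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fp=0, tn=50, fn=0))
        assert np.isnan(m["sensitivity"]["percent"])
        assert m["specificity"]["percent"] == 100.0

    def test_ci_method_named(self):
        m = confusion_metrics(ConfusionCounts(1, 1, 1, 1))
        assert m["ci_method"] == "Clopper-Pearson"


class TestNarrowestSlice:
    def test_exact_match_is_equal(self):
        frame, counts = narrowest_slice_comparison({"k": [100, 90, 95]}, {"k": 90.0})
        assert counts == {"equal": 1, "algorithm_narrower": 0,
                          "reader_narrower": 0, "total": 1, "skipped": 0}

    def test_categories_and_missing_reader(self):
        alg = {"a": [100, 80], "b": [120, 110], "c": [90, 85], "d": [70, 60]}
        reader = {"a": 95.0, "b": 100.0, "c": 85.5}
        frame, counts = narrowest_slice_comparison(alg, reader, tolerance_mm2=1.0)
        assert counts["algorithm_narrower"] == 1  # a: 80 < 95
        assert counts["reader_narrower"] == 1     # b: 110 > 100
        assert counts["equal"] == 1               # c: |85 - 85.5| <= 1
        assert counts["skipped"] == 1             # d has no reader value
        assert counts["total"] == 3

    def test_counts_sum_to_total(self):
        rng = np.random.default_rng(0)
        alg = {i: rng.uniform(50, 150, 11) for i in range(200)}
        reader = {i: float(np.min(alg[i]) + rng.normal(0, 5)) for i in range(200)}
        _, counts = narrowest_slice_comparison(alg, reader)
        assert counts["equal"] + counts["algorithm_narrower"] + counts["reader_narrower"] == 200

    def test_perfect_reader_and_algorithm_all_equal(self):
        """A reader who always picks the true narrowest slice agrees
        with a perfect algorithm on every level."""
        rng = np.random.default_rng(1)
        alg = {i: rng.uniform(60, 140, 11) for i in range(30)}
        reader = {i: float(np.min(alg[i])) for i in range(30)}
        _, counts = narrowest_slice_comparison(alg, reader)
        assert counts["equal"] == 30


def _perfect_slice_table(n_patients=2):
    rows = []
    rng = np.random.default_rng(0)
    for p in range(n_patients):
        for mode in ("lumbar", "abdominal"):
            for level in ("L1-L2", "L2-L3", "L3-L4", "L4-L5", "L5-S1"):
                base = rng.uniform(60, 140)
                for off in range(-5, 6):
                    dsa = base + abs(off) * 3.0
                    rows.append({"patient_id": f"p{p}", "mode": mode, "level": level,
                                 "offset_mm": off, "dsa_pred": dsa, "dsa_true": dsa,
                                 "dice": 1.0})
    return pd.DataFrame(rows)


class TestEvaluateTestset:
    def test_perfect_predictions(self):
        table = _perfect_slice_table()
        rep = evaluate_testset(table)
        overall = rep.segmentation[rep.segmentation.stratum == "Overall CT"].iloc[0]
        assert overall.dsc_mean == 1.0
        cls = rep.classification.set_index("stratum")
        assert cls.loc["Overall CT", "accuracy_pct"] == 100.0
        assert cls.loc["Severe stenosis CT", "accuracy_pct"] == 100.0

    def test_stratum_row_arithmetic(self):
        table = _perfect_slice_table(n_patients=3)
        rep = evaluate_testset(table)
        seg = rep.segmentation.set_index("stratum")
        assert seg.loc["Overall CT", "n_slices"] == 3 * 2 * 5 * 11
        assert seg.loc["Lumbar CT", "n_slices"] == 3 * 5 * 11
        assert len(rep.level_table) == 3 * 2 * 5

    def test_incomplete_level_rejected(self):
        table = _perfect_slice_table().iloc[:-1]
        with pytest.raises(ValueError, match="11"):
            evaluate_testset(table)

    def test_render_contains_ci_parentheses_and_brackets(self):
        text = evaluate_testset(_perfect_slice_table()).render()
        assert "(" in text and "[" in text
        assert "Clopper-Pearson" in text
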