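import math

import numpy as np
import pytest
from scipy.stats import ttest_ind

from mirsig import (
    CohortDesign,
    ConfusionCounts,
    PipelineConfig,
    SubtypeSignature,
    compute_metrics,
    consolidate_signatures,
    generate_cohort,
    inner_loop_select,
    rank_features,
    train_ovr_svm,
)
from mirsig.dlcv import dlcv, train_outer_fold


class TestComputeMetrics:
    def test_hand_worked_confusion(self):
        m = compute_metrics(ConfusionCounts(tp=9, fn=1, tn=85, fp=5))
        assert m["sensitivity"] == pytest.approx(90.0)
        assert m["specificity"] == pytest.approx(100 * 85 / 90)
        assert m["ppv"] == pytest.approx(100 * 9 / 14)
        assert m["npv"] == pytest.approx(100 * 85 / 86)
        assert m["accuracy"] == pytest.approx(94.0)

    def test_perfect_prediction(self):
        m = compute_metrics(ConfusionCounts(tp=10, tn=90))
        assert all(v == 100.0 for v in m.values())

    def test_degenerate_denominator_flagged_nan(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert math.isnan(m["ppv"])
        assert m["sensitivity"] == 0.0

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts())

    @pytest.mark.parametrize("trial", range(200))
    def test_agrees_with_direct_counting(self, trial):
        rng = np.random.default_rng(3000 + trial)
        n = int(rng.integers(2, 40))
        y_true = rng.integers(0, 2, n)
        y_pred = rng.integers(0, 2, n)
        c = ConfusionCounts()
        c.add_predictions(y_true, y_pred)
        m = compute_metrics(c)
        # brute-force loop oracle
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
        tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
        for name, num, den in [
            ("sensitivity", tp, tp + fn),
            ("specificity", tn, tn + fp),
            ("ppv", tp, tp + fp),
            ("npv", tn, tn + fn),
            ("accuracy", tp + tn, n),
        ]:
            if den == 0:
                assert math.isnan(m[name])
            else:
                assert m[name] == pytest.approx(100 * num / den)


class TestRankFeatures:
    def test_matches_scipy_welch_t(self, rng):
        values = rng.normal(size=(5, 10))
        y = np.array([0] * 5 + [1] * 5)
        order = rank_features(values, y, [f"f{i}" for i in range(5)])
        t = np.abs(ttest_ind(values[:, y == 1], values[:, y == 0],
                             axis=1, equal_var=False).statistic)
        assert list(order) == list(np.argsort(-t, kind="stable"))

    def test_zero_variance_nonzero_gap_ranks_first(self):
        values = np.array(
            [
                [0.0, 0.0, 0.0, 1.0, 1.0, 1.0],  # infinite t
                [0.1, -0.2, 0.4, 0.5, 0.1, 0.6],
                [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],  # identical in both classes
            ]
        )
        y = np.array([0, 0, 0, 1, 1, 1])
        order = rank_features(values, y, ["a", "b", "c"])
        assert order[0] == 0 and order[-1] == 2

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            rank_features(np.zeros((2, 3)), np.array([0, 0, 1]), ["a", "b"])


class TestSvm:
    def test_separable_1d_boundary_and_flip(self):
        values = np.array([[-2.0, -1.5, -1.0, 1.0, 1.5, 2.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = train_ovr_svm(values, y, [0])
        assert np.array_equal(model.predict(values), y)
        flipped = train_ovr_svm(values, 1 - y, [0])
        assert np.array_equal(flipped.predict(values), 1 - y)

    def test_symmetric_toy_matches_analytic_soft_margin(self):
        # x = (-3,-1,1,3)/sd after standardization; by symmetry b=0 and the
        # C=1 hinge optimum is w = 2/sqrt(5): objective w^2/2 + 2(1 - w/sqrt5)
        # minimized at w = 2/sqrt(5) (inner points stay inside the margin).
        values = np.array([[-3.0, -1.0, 1.0, 3.0]])
        y = np.array([0, 0, 1, 1])
        model = train_ovr_svm(values, y, [0], c=1.0)
        assert model.intercept == pytest.approx(0.0, abs=1e-6)
        assert model.coef[0] == pytest.approx(2 / math.sqrt(5), abs=1e-6)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            train_ovr_svm(np.zeros((2, 4)), np.array([0, 0, 1, 1]), [])


class TestInnerLoop:
    def test_grid_of_one(self, rng):
        values = rng.normal(size=(6, 24))
        values[0, 12:] += 4
        y = np.array([0] * 12 + [1] * 12)
        m, scores = inner_loop_select(values, y, [f"f{i}" for i in range(6)],
                                      (1,), 3, seed=0)
        assert m == 1 and set(scores) == {1}

    def test_saturated_accuracy_breaks_ties_to_largest(self, rng):
        # two perfectly separating features: every grid size achieves 100%
        values = rng.normal(scale=0.1, size=(4, 30))
        y = np.array([0] * 15 + [1] * 15)
        values[0, y == 1] += 10
        values[1, y == 1] += 10
        m, scores = inner_loop_select(values, y, list("abcd"), (1, 2, 4), 5, seed=1)
        assert scores[1] == scores[2] == scores[4] == 1.0
        assert m == 4

    def test_refolds_when_class_smaller_than_folds(self, rng, caplog):
        values = rng.normal(size=(5, 20))
        y = np.array([1, 1, 1] + [0] * 17)
        m, _ = inner_loop_select(values, y, [f"f{i}" for i in range(5)],
                                 (1, 2), 5, seed=0)
        assert m in (1, 2)

    def test_impossible_folds_error(self, rng):
        values = rng.normal(size=(5, 10))
        y = np.array([1] + [0] * 9)
        with pytest.raises(ValueError):
            inner_loop_select(values, y, [f"f{i}" for i in range(5)], (1,), 5, seed=0)


@pytest.fixture(scope="module")
def cohort_and_config():
    design = CohortDesign(
        n_features=120,
        group_sizes={"MLL": 14, "t_8_21": 12, "NPM1": 10, "other": 24},
        signature_sizes={"MLL": 10, "t_8_21": 8, "NPM1": 5},
        effect_log2=3.0,
        missing_rate=0.0,
        rng_seed=7,
    )
    cfg = PipelineConfig(dlcv_runs=8, rng_seed=7, min_group_size=10,
                         feature_grid=(1, 2, 3, 5, 8, 12, 18, 27))
    return generate_cohort(design), cfg


class TestDlcv:
    def test_strong_signal_metrics_and_recovery(self, cohort_and_config):
        (x, ann, truth), cfg = cohort_and_config
        report = dlcv(x, ann, "MLL", cfg)
        assert report.mean_metrics["sensitivity"] >= 90
        assert report.mean_metrics["specificity"] >= 90
        planted = truth.signature_features("MLL")
        recovered = sum(
            1 for f in planted if report.selection_frequency.get(f, 0) >= 0.5
        )
        assert recovered >= 0.8 * len(planted)

    def test_determinism_identical_reports(self, cohort_and_config):
        (x, ann, _), cfg = cohort_and_config
        r1 = dlcv(x, ann, "NPM1", cfg)
        r2 = dlcv(x, ann, "NPM1", cfg)
        assert r1.to_dict() == r2.to_dict()

    def test_leakage_guard_test_sample_cannot_touch_model(self, cohort_and_config):
        """Perturbing a held-out sample leaves the fold's model bit-identical."""
        (x, ann, _), cfg = cohort_and_config
        y = ann.binary_labels("MLL")
        n = len(y)
        train_idx = np.arange(n - 8)
        test_idx = np.arange(n - 8, n)
        m1 = train_outer_fold(x.values, y, train_idx, x.feature_ids, cfg, fold_seed=5)
        perturbed = x.values.copy()
        perturbed[:, test_idx] += 1e6  # absurd outlier in every held-out sample
        m2 = train_outer_fold(perturbed, y, train_idx, x.feature_ids, cfg, fold_seed=5)
        assert np.array_equal(m1.feature_idx, m2.feature_idx)
        assert np.array_equal(m1.coef, m2.coef)
        assert m1.intercept == m2.intercept
        assert np.array_equal(m1.mean, m2.mean)

    def test_small_group_refused(self, cohort_and_config):
        (x, ann, _), cfg = cohort_and_config
        with pytest.raises(ValueError, match="minimum group size"):
            dlcv(x, ann, "t_15_17", cfg)


class TestConsolidation:
    def _sig(self, subtype, names):
        return SubtypeSignature(subtype, [(n, "up", 1.0) for n in names])

    def test_disjoint_union(self):
        out = consolidate_signatures(
            [self._sig("MLL", ["a", "b", "c"]), self._sig("NPM1", ["d", "e", "f", "g"])]
        )
        assert out["union_size"] == 7

    def test_identical_signatures_collapse(self):
        out = consolidate_signatures(
            [self._sig("MLL", ["a", "b"]), self._sig("NPM1", ["a", "b"])]
        )
        assert out["union_size"] == 2
        assert set(out["members"]["a"]) == {"MLL", "NPM1"}

    def test_partial_overlap_smaller_than_sum(self):
        # sizes mimicking the study's per-subtype signatures with shared members
        sizes = {"MLL": 37, "t_8_21": 14, "inv_16": 17, "t_15_17": 14,
                 "CEBPA_dm": 18, "NPM1": 5}
        shared = ["miR-196b", "miR-126s", "miR-9"]
        sigs = []
        at = 0
        for st, k in sizes.items():
            names = [f"m{at + i}" for i in range(k - 2)] + shared[:2]
            at += k
            sigs.append(self._sig(st, names))
        out = consolidate_signatures(sigs)
        assert out["union_size"] < sum(sizes.values())
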