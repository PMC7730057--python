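import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn import metrics as sk_metrics

from busfeat.classify_eval import (
    ConfusionCounts,
    SvmConfig,
    grid_search_cv,
    make_mcc_evaluator,
    metrics,
    paired_ttest,
    predict,
    roc_auc,
    sigma_to_gamma,
    train_final,
)


def blobs(n=60, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    x = np.vstack(
        [rng.normal(0, 1, (half, 2)), rng.normal(sep, 1, (n - half, 2))]
    )
    y = np.array(["benign"] * half + ["malignant"] * (n - half))
    return pd.DataFrame(x, columns=["u", "v"]), y


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
        assert all(np.isclose(v, 1.0) for v in m.values())

    def test_chance_level(self):
        m = metrics(ConfusionCounts(tp=25, tn=25, fp=25, fn=25))
        assert np.isclose(m["accuracy"], 0.5) and np.isclose(m["mcc"], 0.0)

    def test_hand_computed_table(self):
        m = metrics(ConfusionCounts(tp=90, tn=80, fp=20, fn=10))
        assert np.isclose(m["sensitivity"], 0.90)
        assert np.isclose(m["specificity"], 0.80)
        assert np.isclose(m["ppv"], 9 / 11)
        assert np.isclose(m["npv"], 8 / 9)
        assert np.isclose(m["mcc"], (90 * 80 - 20 * 10) / math.sqrt(110 * 100 * 100 * 90))

    def test_zero_denominator_flagged_as_zero(self):
        with pytest.warns(UserWarning, match="zero denominator"):
            m = metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert m["sensitivity"] == 0.0 and m["ppv"] == 0.0

    def test_matches_sklearn_on_random_tables(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 40, 4))
            if tp + tn + fp + fn == 0 or (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn) == 0:
                continue
            y_true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
            y_pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
            m = metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
            assert np.isclose(m["mcc"], sk_metrics.matthews_corrcoef(y_true, y_pred))
            assert np.isclose(m["accuracy"], sk_metrics.accuracy_score(y_true, y_pred))

    def test_mcc_sign_flips_under_label_swap(self):
        c = ConfusionCounts(tp=30, tn=20, fp=10, fn=5)
        swapped = ConfusionCounts(tp=c.tn, tn=c.tp, fp=c.fn, fn=c.fp)
        assert np.isclose(metrics(c)["mcc"], metrics(swapped)["mcc"])
        neg = ConfusionCounts(tp=c.fn, tn=c.fp, fp=c.tn, fn=c.tp)
        assert np.isclose(metrics(c)["mcc"], -metrics(neg)["mcc"])
        assert np.isclose(metrics(c)["accuracy"], metrics(swapped)["accuracy"])


class TestGridSearch:
    def test_default_grid_has_399_pairs(self):
        cfg = SvmConfig()
        assert len(cfg.c_grid) == 21 and len(cfg.sigma_grid) == 19
        assert cfg.n_pairs == 399
        assert cfg.c_grid[0] == 2.0**-5 and cfg.c_grid[-1] == 2.0**15
        assert cfg.sigma_grid[0] == 2.0**-15 and cfg.sigma_grid[-1] == 2.0**3

    def test_gamma_mapping(self):
        assert np.isclose(sigma_to_gamma(1.0), 0.5)
        assert np.isclose(sigma_to_gamma(2.0), 1 / 8)

    def test_separable_blobs_reach_mcc_one(self):
        x, y = blobs(n=60, sep=10.0)
        small = SvmConfig(c_grid=(1.0, 8.0), sigma_grid=(0.5, 1.0, 4.0))
        report = grid_search_cv(x, y, small, folds=5, seed=0)
        assert report.pooled_mcc == 1.0
        assert report.mean_metrics["accuracy"] == 1.0
        assert report.auc == 1.0

    def test_permuted_labels_near_chance(self):
        x, y = blobs(n=60, sep=10.0)
        small = SvmConfig(c_grid=(1.0,), sigma_grid=(1.0,))
        rng = np.random.default_rng(4)
        mccs = []
        for s in range(8):
            yp = rng.permutation(y)
            mccs.append(grid_search_cv(x, yp, small, folds=5, seed=s).pooled_mcc)
        assert abs(np.mean(mccs)) < 0.25

    def test_fold_assignment_reproducible_and_partitioning(self):
        x, y = blobs(n=40, sep=5.0, seed=2)
        small = SvmConfig(c_grid=(1.0,), sigma_grid=(1.0,))
        r1 = grid_search_cv(x, y, small, folds=5, seed=9)
        r2 = grid_search_cv(x, y, small, folds=5, seed=9)
        assert r1.fold_assignment == r2.fold_assignment
        flat = sorted(i for fold in r1.fold_assignment for i in fold)
        assert flat == list(range(40))  # each sample tested exactly once

    def test_too_few_per_class_rejected(self):
        x, y = blobs(n=12, sep=5.0)
        with pytest.raises(ValueError, match="class"):
            grid_search_cv(x, y, SvmConfig(c_grid=(1.0,), sigma_grid=(1.0,)), folds=10)


class TestTrainPredict:
    def test_training_set_mcc_one_on_separable(self):
        x, y = blobs(n=40, sep=8.0)
        model = train_final(x, y, c=1.0, sigma=1.0)
        pred, scores = predict(model, x)
        assert np.array_equal(pred, (y == "malignant").astype(int))
        assert scores.shape == (40,)

    def test_single_sample_prediction(self):
        x, y = blobs(n=30, sep=8.0)
        model = train_final(x, y, c=1.0, sigma=1.0)
        pred, score = predict(model, x.iloc[[0]])
        assert pred.shape == (1,) and score.shape == (1,)

    def test_feature_name_mismatch_rejected(self):
        x, y = blobs(n=30, sep=8.0)
        model = train_final(x, y, c=1.0, sigma=1.0)
        bad = x.rename(columns={"u": "w"})
        with pytest.raises(ValueError, match="feature names"):
            predict(model, bad)


class TestRocAuc:
    def test_perfect_and_inverted_ordering(self):
        y = np.array([0, 0, 1, 1])
        _, auc = roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), y)
        assert auc == 1.0
        _, auc = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), y)
        assert auc == 0.0

    def test_equals_mann_whitney_on_random_scores(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            n = int(rng.integers(10, 60))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            scores = np.round(rng.normal(size=n), 1)  # coarse: force ties
            _, auc = roc_auc(scores, y)
            u = stats.mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
            assert np.isclose(auc, u / (y.sum() * (n - y.sum())))

    def test_interleaved_random_scores_near_half(self):
        rng = np.random.default_rng(17)
        y = np.array([0, 1] * 500)
        _, auc = roc_auc(rng.normal(size=1000), y)
        assert abs(auc - 0.5) < 0.05

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestPairedTtest:
    def test_constant_shift_degenerate_t(self):
        b = np.linspace(0.7, 0.9, 10)
        assert paired_ttest(b + 0.1, b) < 1e-6

    def test_identical_sequences_flagged_nan(self):
        a = np.array([0.8, 0.9, 0.85])
        with pytest.warns(UserWarning, match="identical"):
            assert math.isnan(paired_ttest(a, a))

    def test_textbook_differences(self):
        # differences 1..5: mean 3, sd 1.5811, t = 3*sqrt(5)/1.5811 = 4.2426
        b = np.zeros(5)
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        t = 3.0 * math.sqrt(5) / math.sqrt(2.5)
        expected = 2 * stats.t.sf(t, df=4)
        assert np.isclose(paired_ttest(a, b), expected)


class TestEvaluator:
    def test_fast_evaluator_scores_subsets(self):
        x, y = blobs(n=40, sep=8.0, seed=3)
        x["junk"] = np.random.default_rng(0).normal(size=40)
        ev = make_mcc_evaluator(x, y, folds=5, seed=0)
        assert ev(["u", "v"]) == 1.0
        assert ev(["junk"]) < 0.5

    def test_full_mode_at_least_as_good_as_fast(self):
        x, y = blobs(n=40, sep=2.0, seed=5)
        fast = make_mcc_evaluator(x, y, folds=5, seed=1, mode="fast")
        full = make_mcc_evaluator(
            x, y, folds=5, seed=1, mode="full",
            config=SvmConfig(c_grid=(0.5, 1.0, 8.0), sigma_grid=(0.5, 1.0, 2.0)),
        )
        assert full(["u", "v"]) >= fast(["u", "v"]) - 1e-12
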