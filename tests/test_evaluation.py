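"""Metrics (binary, micro-averaged, regression) and the evaluation harnesses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.linear_model import LogisticRegression, LinearRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from mixcarc.errors import LeakageError
from mixcarc.evaluation import (
    ConfusionCounts,
    binary_metrics,
    check_disjoint,
    disjoint_eval,
    micro_auc,
    micro_metrics,
    rank_auc,
    regression_metrics,
    repeated_holdout,
)


class TestBinaryMetrics:
    def test_perfect_predictions(self):
        m = binary_metrics(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert m["accuracy"] == m["sensitivity"] == m["specificity"] == m["precision"] == 1.0

    def test_ratio_arithmetic(self):
        m = binary_metrics(ConfusionCounts(tp=3, fn=1, tn=4, fp=2))
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(2 / 3)
        assert m["accuracy"] == pytest.approx(0.7)
        assert m["precision"] == pytest.approx(0.6)

    def test_undefined_ratios_reported_as_missing(self):
        m = binary_metrics(ConfusionCounts(tp=0, fp=2, tn=3, fn=0))
        assert m["sensitivity"] is None  # no positives: undefined, not 0
        m = binary_metrics(ConfusionCounts(tp=2, fp=0, tn=0, fn=1))
        assert m["specificity"] is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)


class TestRankAuc:
    def test_extremes(self):
        y = [1, 1, 0, 0]
        assert rank_auc(y, [0.9, 0.8, 0.2, 0.1]) == 1.0
        assert rank_auc(y, [0.1, 0.2, 0.8, 0.9]) == 0.0

    def test_single_class_undefined(self):
        assert rank_auc([1, 1], [0.2, 0.4]) is None

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_trapezoidal_roc_integration(self, seed):
        """Mann-Whitney rank AUC equals sklearn's trapezoidal ROC AUC, ties included."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        y = rng.integers(0, 2, size=n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        assert rank_auc(y, scores) == pytest.approx(roc_auc_score(y, scores), abs=1e-10)


def brute_force_micro(y, p, K):
    """Independent oracle: loop over samples and classes, pool, then divide."""
    tp = fp = tn = fn = 0
    for yi, pi in zip(y, p):
        for k in range(K):
            t, q = yi == k, pi == k
            tp += t and q
            fp += (not t) and q
            fn += t and (not q)
            tn += (not t) and (not q)
    total = tp + fp + tn + fn
    return {
        "micro_accuracy": (tp + tn) / total,
        "micro_sensitivity": tp / (tp + fn),
        "micro_specificity": tn / (tn + fp),
        "micro_precision": tp / (tp + fp),
    }


class TestMicroMetrics:
    @pytest.mark.parametrize("K", [2, 3, 4])
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_pooling(self, K, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 80))
        y = rng.integers(0, K, size=n)
        p = rng.integers(0, K, size=n)
        got = micro_metrics(y, p, K)
        expect = brute_force_micro(y, p, K)
        for key, val in expect.items():
            assert got[key] == pytest.approx(val, abs=1e-12)

    @pytest.mark.parametrize("K", [2, 3, 4])
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_single_label_identities(self, K, seed):
        """micro-sens = micro-prec = a; micro-acc = 1 - 2(1-a)/K; micro-spec = 1 - (1-a)/(K-1)."""
        rng = np.random.default_rng(seed)
        y = rng.integers(0, K, size=60)
        p = rng.integers(0, K, size=60)
        m = micro_metrics(y, p, K)
        a = m["accuracy"]
        assert m["micro_sensitivity"] == pytest.approx(a, abs=1e-12)
        assert m["micro_precision"] == pytest.approx(a, abs=1e-12)
        assert m["micro_accuracy"] == pytest.approx(1 - 2 * (1 - a) / K, abs=1e-12)
        assert m["micro_specificity"] == pytest.approx(1 - (1 - a) / (K - 1), abs=1e-12)

    def test_published_three_class_triple(self):
        """Overall accuracy 96.03% at K=3 pools to micro-accuracy 97.35% and micro-specificity 98.01%."""
        n, correct = 10_000, 9_603
        y = np.zeros(n, dtype=int)
        y[3_000:6_000] = 1
        y[6_000:] = 2
        p = y.copy()
        wrong = np.arange(n - (n - correct), n)  # tail samples mispredicted
        p[wrong] = (y[wrong] + 1) % 3
        m = micro_metrics(y, p, 3)
        assert m["accuracy"] == pytest.approx(0.9603)
        assert 100 * m["micro_accuracy"] == pytest.approx(97.35, abs=0.0051)
        assert 100 * m["micro_specificity"] == pytest.approx(98.01, abs=0.0051)
        assert 100 * m["micro_sensitivity"] == pytest.approx(96.03, abs=1e-9)

    def test_all_correct(self):
        m = micro_metrics([0, 1, 2], [0, 1, 2], 3)
        assert all(v == 1.0 for v in m.values())

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            micro_metrics([0, 3], [0, 1], 3)
        with pytest.raises(ValueError):
            micro_metrics([0, 1], [0], 2)

    def test_micro_auc_perfect(self):
        prob = np.eye(3)[[0, 1, 2, 2]]
        assert micro_auc([0, 1, 2, 2], prob) == 1.0


class TestRegressionMetrics:
    def test_perfect_fit(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m == {"mse": 0.0, "mae": 0.0, "r2": 1.0}

    def test_mean_predictor_has_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        m = regression_metrics(y, np.full(4, y.mean()))
        assert m["r2"] == pytest.approx(0.0)

    def test_unit_residuals(self):
        m = regression_metrics([0.0, 0.0], [1.0, -1.0])
        assert m["mse"] == 1.0 and m["mae"] == 1.0

    def test_constant_truth_r2_undefined(self):
        assert regression_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])["r2"] is None


def _binary_data(n=200, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    X = rng.normal(size=(n, 5)) + 2.0 * y[:, None]
    return X, y


class TestRepeatedHoldout:
    def test_single_iteration_equals_manual_split(self):
        X, y = _binary_data()
        est = LogisticRegression(max_iter=500)
        report = repeated_holdout(est, X, y, "binary", n_iter=1, base_seed=3)
        X_tr, X_te, y_tr, y_te = train_test_split(X, y, test_size=0.2, random_state=3)
        manual = LogisticRegression(max_iter=500).fit(X_tr, y_tr)
        acc = (manual.predict(X_te) == y_te).mean()
        assert report.aggregates["accuracy"] == pytest.approx(acc)

    def test_same_base_seed_reproduces_report(self):
        X, y = _binary_data()
        est = LogisticRegression(max_iter=500)
        a = repeated_holdout(est, X, y, "binary", n_iter=5, base_seed=1)
        b = repeated_holdout(est, X, y, "binary", n_iter=5, base_seed=1)
        assert a.records == b.records and a.aggregates == b.aggregates

    def test_aggregates_are_mean_of_records(self):
        X, y = _binary_data()
        report = repeated_holdout(LogisticRegression(max_iter=500), X, y, "binary",
                                  n_iter=4, base_seed=0)
        for metric, value in report.aggregates.items():
            vals = [r["value"] for r in report.records
                    if r["metric"] == metric and r["value"] is not None]
            assert value == pytest.approx(np.mean(vals), abs=1e-12)

    def test_permuted_labels_score_at_chance(self):
        """Null simulation: labels re-permuted each iteration, so the 30
        accuracies are independent draws; their mean sits within 3 SE of 0.5."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(400, 5))
        y0 = np.repeat([0, 1], 200)
        accs = []
        for i in range(30):
            y = np.random.default_rng(1000 + i).permutation(y0)
            rep = repeated_holdout(LogisticRegression(max_iter=500), X, y, "binary",
                                   n_iter=1, base_seed=i)
            accs.append(rep.aggregates["accuracy"])
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 0.5) <= 3 * max(se, 1e-6)

    def test_regression_task_and_cv(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 4))
        y = X @ np.array([1.0, -2.0, 0.0, 0.5]) + 0.01 * rng.normal(size=120)
        report = repeated_holdout(LinearRegression(), X, y, "regression",
                                  n_iter=2, base_seed=0, cv_folds=5)
        assert report.aggregates["r2"] > 0.99
        assert report.aggregates["cv_r2"] > 0.99

    def test_report_serializes(self, tmp_path):
        X, y = _binary_data(n=80)
        report = repeated_holdout(LogisticRegression(max_iter=500), X, y, "binary",
                                  n_iter=2, base_seed=0)
        path = tmp_path / "report.json"
        report.to_json(path)
        assert path.exists()
        frame = report.to_frame()
        assert {"iteration", "seed", "metric", "value"} <= set(frame.columns)


class TestDisjointEval:
    def test_overlap_names_the_chemical(self):
        with pytest.raises(LeakageError, match="c03"):
            check_disjoint(["c01", "c02", "c03"], ["c03", "c04"])

    def test_disjoint_happy_path_zero_dispersion(self):
        X_tr, y_tr = _binary_data(n=150, seed=0)
        X_te, y_te = _binary_data(n=60, seed=1)
        report = disjoint_eval(
            LogisticRegression(max_iter=500), X_tr, y_tr, X_te, y_te,
            train_chem_ids=["a", "b"], test_chem_ids=["c", "d"],
            task="binary", n_iter=3, base_seed=0,
        )
        # deterministic learner (ignores random_state): identical iterations
        assert report.dispersion["accuracy"] == 0.0
        assert 0.5 < report.aggregates["accuracy"] <= 1.0

    def test_leakage_blocks_evaluation(self):
        X, y = _binary_data(n=50)
        with pytest.raises(LeakageError):
            disjoint_eval(LogisticRegression(), X, y, X, y,
                          train_chem_ids=["a"], test_chem_ids=["a"],
                          task="binary", n_iter=1)
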