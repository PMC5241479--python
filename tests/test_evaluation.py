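"""Splitting, confusion metrics, ROC/AUC (Mann-Whitney oracle), and the
four-classifier baseline panel."""

import numpy as np
import pandas as pd
import pytest

from tonguelab import (
    LabeledDatasetSpec,
    confusion_metrics,
    make_feature_dataset,
    roc_auc,
    run_baselines,
    split_dataset,
)
from tonguelab.evaluation import BASELINE_ORDER, evaluate_scores


def mann_whitney_auc(y_true, scores):
    """All-pairs probability a positive outranks a negative, ties 1/2."""
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


class TestSplit:
    def test_exact_rounding_small(self):
        df = pd.DataFrame({"x": range(10), "label": [0, 1] * 5})
        train, test = split_dataset(df, 0.8, seed=0)
        assert len(train) == 8 and len(test) == 2

    def test_stratified_balanced_counts(self):
        """531/531 at 80%: round(0.8*531)=425 training rows per class."""
        df = pd.DataFrame({"x": range(1062), "label": [0] * 531 + [1] * 531})
        train, test = split_dataset(df, 0.8, seed=1)
        assert (train["label"] == 0).sum() == 425
        assert (train["label"] == 1).sum() == 425
        assert len(test) == 1062 - 850

    def test_disjoint_exhaustive(self):
        df = make_feature_dataset(LabeledDatasetSpec(n_minority=30, n_majority=70, seed=2))
        df["row_id"] = range(len(df))
        train, test = split_dataset(df, 0.8, seed=2)
        ids = set(train["row_id"]) | set(test["row_id"])
        assert len(ids) == len(df)
        assert not (set(train["row_id"]) & set(test["row_id"]))

    def test_seeded_determinism(self):
        df = make_feature_dataset(LabeledDatasetSpec(seed=3))
        a_train, a_test = split_dataset(df, 0.8, seed=5)
        b_train, b_test = split_dataset(df, 0.8, seed=5)
        assert a_train.equals(b_train) and a_test.equals(b_test)

    def test_tiny_stratum_rejected(self):
        df = pd.DataFrame({"x": [1, 2, 3], "label": [0, 0, 1]})
        with pytest.raises(ValueError):
            split_dataset(df, 0.8, stratified=True)

    def test_bad_fraction_rejected(self):
        df = pd.DataFrame({"x": [1, 2], "label": [0, 1]})
        with pytest.raises(ValueError):
            split_dataset(df, 1.0)


class TestConfusionMetrics:
    def test_worked_example(self):
        y_true = np.array([1] * 4 + [0] * 6)
        y_pred = np.array([1, 1, 1, 0, 1, 1, 0, 0, 0, 0])
        m = confusion_metrics(y_true, y_pred)
        assert (m["tp"], m["fn"], m["tn"], m["fp"]) == (3, 1, 4, 2)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(2 / 3)
        assert m["accuracy"] == pytest.approx(0.70)

    def test_perfect_prediction(self):
        y = np.array([0, 1, 1, 0, 1])
        m = confusion_metrics(y, y)
        assert m["accuracy"] == m["sensitivity"] == m["specificity"] == 1.0

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(4)
        y_true = rng.integers(0, 2, 50)
        y_pred = rng.integers(0, 2, 50)
        m = confusion_metrics(y_true, y_pred)
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
        tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
        assert m["accuracy"] == pytest.approx((tp + tn) / 50)
        assert m["tp"] == tp and m["tn"] == tn

    def test_accuracy_is_prevalence_weighted_mean_of_rates(self):
        rng = np.random.default_rng(5)
        y_true = rng.integers(0, 2, 80)
        y_pred = rng.integers(0, 2, 80)
        m = confusion_metrics(y_true, y_pred)
        prev = y_true.mean()
        assert m["accuracy"] == pytest.approx(
            prev * m["sensitivity"] + (1 - prev) * m["specificity"]
        )

    def test_absent_class_flagged(self):
        m = confusion_metrics(np.ones(5, int), np.ones(5, int))
        assert np.isnan(m["specificity"]) and m["sensitivity"] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [])


class TestRocAuc:
    def test_perfect_ranking(self):
        y = np.array([0, 0, 1, 1])
        pts, auc = roc_auc(y, np.array([0.1, 0.2, 0.8, 0.9]))
        assert auc == 1.0
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)

    def test_anti_ranking(self):
        y = np.array([0, 0, 1, 1])
        _, auc = roc_auc(y, np.array([0.9, 0.8, 0.2, 0.1]))
        assert auc == 0.0

    def test_monotone_curve(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 60)
        pts, _ = roc_auc(y, rng.normal(size=60))
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)

    def test_equals_mann_whitney_with_ties(self):
        """Trapezoid AUC = tie-corrected all-pairs statistic to 1e-12,
        including heavily tied scores."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            y = rng.integers(0, 2, 40)
            if len(np.unique(y)) < 2:
                continue
            scores = rng.integers(0, 5, 40).astype(float)  # many ties
            _, auc = roc_auc(y, scores)
            assert auc == pytest.approx(mann_whitney_auc(y, scores), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.zeros(5, int), np.arange(5.0))
        with pytest.raises(ValueError):
            roc_auc(np.array([0, 1]), np.array([0.5, np.inf]))


class TestBaselines:
    def _xy(self, sep, seed=0, n=120):
        df = make_feature_dataset(
            LabeledDatasetSpec(n_minority=n // 2, n_majority=n // 2,
                               n_features=5, class_separation=sep, seed=seed)
        )
        X = df.drop(columns="label").to_numpy()
        y = df["label"].to_numpy()
        return X[: int(0.8 * n)], y[: int(0.8 * n)], X[int(0.8 * n):], y[int(0.8 * n):]

    def test_separable_data_all_accurate(self):
        from tonguelab import GASVC

        Xtr, ytr, Xte, yte = self._xy(10.0, seed=1)
        report = run_baselines(
            Xtr, ytr, Xte, yte,
            gasvm=GASVC(population_size=5, generations=3, cv_folds=3, random_state=0),
        )
        assert list(report) == list(BASELINE_ORDER)
        for name in BASELINE_ORDER:
            assert report[name]["accuracy"] >= 0.95, name

    def test_uninformative_features_near_chance_auc(self):
        from tonguelab import GASVC

        aucs = {name: [] for name in BASELINE_ORDER}
        for seed in range(3):
            Xtr, ytr, Xte, yte = self._xy(0.0, seed=seed, n=160)
            report = run_baselines(
                Xtr, ytr, Xte, yte,
                gasvm=GASVC(population_size=4, generations=2, cv_folds=3, random_state=seed),
            )
            for name in BASELINE_ORDER:
                aucs[name].append(report[name]["auc"])
        for name, vals in aucs.items():
            assert 0.35 <= np.mean(vals) <= 0.65, (name, vals)

    def test_report_invariants_hold_for_every_classifier(self):
        from tonguelab import GASVC

        Xtr, ytr, Xte, yte = self._xy(2.0, seed=2)
        report = run_baselines(
            Xtr, ytr, Xte, yte,
            gasvm=GASVC(population_size=4, generations=2, cv_folds=3, random_state=0),
        )
        for name, m in report.items():
            n = m["tp"] + m["tn"] + m["fp"] + m["fn"]
            assert m["accuracy"] == pytest.approx((m["tp"] + m["tn"]) / n)
            assert 0.0 <= m["auc"] <= 1.0
            pts = np.asarray(m["roc"])
            assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
            assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)

    def test_negative_class_curve_mirrors_positive(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 50)
        scores = rng.normal(size=50)
        rep = evaluate_scores(y, (scores > 0).astype(int), scores)
        assert rep["auc_negative_class"] == pytest.approx(rep["auc"], abs=1e-12)

    def test_classifier_failure_reported_in_band(self):
        # one test row only: k-NN with k=5 still works, but a broken GA-SVM
        # (unfitted, zero generations on a single-class train set) must not
        # abort the others
        Xtr = np.zeros((6, 2))
        ytr = np.zeros(6, int)  # single class: GA-SVM and NB may fail
        Xte = np.zeros((2, 2))
        yte = np.array([0, 1])
        report = run_baselines(Xtr, ytr, Xte, yte)
        assert set(report) == set(BASELINE_ORDER)
        assert any("error" in entry for entry in report.values())
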