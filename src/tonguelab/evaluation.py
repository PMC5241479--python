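"""Train/test splitting, confusion metrics, ROC/AUC, and baseline panels.

The positive class throughout is the diabetes-analog label 1; sensitivity is
the true-positive rate and specificity the true-negative rate.  The ROC
curve is traced over every distinct score threshold (ties stepped
simultaneously) and AUC is the trapezoid area, which equals the normalized
Mann-Whitney pair statistic with ties counted one half.

``run_baselines`` fits k-NN, Gaussian Naive Bayes, a one-hidden-layer
backpropagation network, and the GA-SVM on identical training data and
reports all four on identical test data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier

from .gasvm import GASVC

__all__ = [
    "split_dataset",
    "confusion_metrics",
    "roc_auc",
    "evaluate_scores",
    "run_baselines",
    "plot_roc",
    "BASELINE_ORDER",
]

BASELINE_ORDER = ("k-NN", "Naive Bayes", "BP-NN", "GA-SVM")


def split_dataset(table: pd.DataFrame, train_fraction: float = 0.8, seed: int = 0,
                  stratified: bool = True, label_col: str = "label"):
    """Disjoint, exhaustive train/test split of a labeled table.

    Stratified by label by default; the per-stratum train count is
    ``round(train_fraction * n)`` (banker's rounding, documented).  Returns
    ``(train, test)`` DataFrames; row assignment is a seeded permutation.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = np.arange(len(table))
    strata = [idx] if not stratified else [
        idx[np.asarray(table[label_col]) == v] for v in np.unique(table[label_col])
    ]
    train_idx, test_idx = [], []
    for s in strata:
        if stratified and len(s) < 2:
            raise ValueError("each stratum needs at least 2 rows for a split")
        perm = rng.permutation(s)
        n_train = int(round(train_fraction * len(s)))
        n_train = min(max(n_train, 1), len(s) - 1)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    train_idx = np.sort(np.concatenate(train_idx))
    test_idx = np.sort(np.concatenate(test_idx))
    return table.iloc[train_idx].reset_index(drop=True), table.iloc[test_idx].reset_index(drop=True)


def confusion_metrics(y_true, y_pred) -> dict:
    """Accuracy, sensitivity (TPR), specificity (TNR) and the confusion
    counts, positive class = 1.  A class absent from ``y_true`` leaves the
    affected rate NaN."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be equal-length and nonempty")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    acc = (tp + tn) / len(y_true)
    return {
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec,
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
    }


def roc_auc(y_true, scores):
    """ROC points and trapezoid AUC, positive class = 1.

    Thresholds are taken at every distinct score; the returned point list
    starts at (0, 0) and ends at (1, 1) and is monotone in both
    coordinates.
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if len(np.unique(y_true)) < 2:
        raise ValueError("both classes must be present to trace a ROC curve")
    fpr, tpr, _ = roc_curve(y_true, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def evaluate_scores(y_true, y_pred, scores) -> dict:
    """Full per-classifier report: confusion metrics plus ROC/AUC for the
    positive class, and the mirrored negative-class curve."""
    report = confusion_metrics(y_true, y_pred)
    points, auc = roc_auc(y_true, scores)
    y_true = np.asarray(y_true).astype(int)
    neg_points, neg_auc = roc_auc(1 - y_true, -np.asarray(scores, dtype=float))
    report["auc"] = auc
    report["roc"] = points.tolist()
    report["roc_negative_class"] = neg_points.tolist()
    report["auc_negative_class"] = neg_auc
    return report


def _positive_proba(clf, X):
    proba = clf.predict_proba(X)
    return proba[:, list(clf.classes_).index(1)]


def run_baselines(X_train, y_train, X_test, y_test, *, knn_k: int = 5,
                  bpnn_hidden: int = 10, bpnn_max_iter: int = 2000,
                  gasvm: GASVC | None = None, seed: int = 0) -> dict:
    """Fit and evaluate the four classifiers on identical data.

    Scores used for the ROC: positive-neighbor fraction (k-NN), posterior
    probability (Naive Bayes), output activation (BP-NN), and decision
    values (GA-SVM).  A classifier that fails is reported with an ``error``
    entry without aborting the rest.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train).astype(int)
    y_test = np.asarray(y_test).astype(int)

    def fit_eval(name):
        if name == "k-NN":
            clf = KNeighborsClassifier(n_neighbors=knn_k).fit(X_train, y_train)
            return clf.predict(X_test), _positive_proba(clf, X_test)
        if name == "Naive Bayes":
            clf = GaussianNB().fit(X_train, y_train)
            return clf.predict(X_test), _positive_proba(clf, X_test)
        if name == "BP-NN":
            clf = MLPClassifier(
                hidden_layer_sizes=(bpnn_hidden,),
                activation="logistic",
                solver="sgd",
                learning_rate_init=0.1,
                max_iter=bpnn_max_iter,
                random_state=seed,
            ).fit(X_train, y_train)
            return clf.predict(X_test), _positive_proba(clf, X_test)
        clf = gasvm or GASVC(random_state=seed)
        if not hasattr(clf, "svm_"):
            clf.fit(X_train, y_train)
        return clf.predict(X_test), clf.decision_function(X_test)

    report = {}
    for name in BASELINE_ORDER:
        try:
            y_pred, scores = fit_eval(name)
            report[name] = evaluate_scores(y_test, y_pred, scores)
        except Exception as exc:  # propagate per-classifier failures in-band
            report[name] = {"error": f"{type(exc).__name__}: {exc}"}
    return report


def plot_roc(report: dict, path):
    """Write a ROC plot (one curve per classifier, positive class) to path."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, entry in report.items():
        if "roc" not in entry:
            continue
        pts = np.asarray(entry["roc"])
        ax.plot(pts[:, 0], pts[:, 1], label=f"{name} (AUC {entry['auc']:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
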