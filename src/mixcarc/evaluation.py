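"""Metrics and the repeated-evaluation harnesses.

Binary metrics come from pooled confusion counts plus a rank-statistic
(Mann-Whitney) AUC. Multiclass performance is micro-averaged: each sample
contributes K one-vs-rest binary decisions, the counts are pooled, and the
ratios are computed on the pool. For single-label data this gives the exact
identities

    micro-sensitivity = micro-precision = overall accuracy a
    micro-accuracy    = 1 - 2 (1 - a) / K
    micro-specificity = 1 - (1 - a) / (K - 1)

because every misclassified sample creates exactly one false positive and
one false negative among its K pooled decisions.

The harnesses repeat an 80/20 shuffled holdout (30 iterations by default,
averaging the per-iteration metrics), or score a fixed compound-disjoint
test set while varying only the learner seed. Undefined metrics (zero
denominators) are reported as missing, never coerced to 0, and excluded
from aggregates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.model_selection import KFold, train_test_split

from .errors import LeakageError


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; ``total`` is the number of evaluated decisions."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def rank_auc(y_true, scores) -> float | None:
    """AUC by the Mann-Whitney rank statistic, ties mid-ranked.

    Returns ``None`` (undefined) when either class is absent.
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)
    rank_sum_pos = float(ranks[y_true == 1].sum())
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def _safe_ratio(num, den) -> float | None:
    return num / den if den else None


def binary_metrics(counts: ConfusionCounts, scores=None, y_true=None) -> dict:
    """Accuracy, sensitivity, specificity, precision, and (given scores) AUC.

    Ratios with a zero denominator are reported as ``None`` (undefined),
    never as 0.
    """
    record = {
        "accuracy": _safe_ratio(counts.tp + counts.tn, counts.total),
        "sensitivity": _safe_ratio(counts.tp, counts.tp + counts.fn),
        "specificity": _safe_ratio(counts.tn, counts.tn + counts.fp),
        "precision": _safe_ratio(counts.tp, counts.tp + counts.fp),
    }
    if scores is not None:
        if y_true is None:
            raise ValueError("AUC needs the per-sample labels alongside the scores")
        record["auc"] = rank_auc(y_true, scores)
    return record


def micro_metrics(true_classes, predicted_classes, n_classes: int) -> dict:
    """Micro-averaged one-vs-rest metrics for single-label multiclass data.

    Every sample contributes ``n_classes`` binary one-vs-rest decisions;
    counts are pooled before computing the ratios. The overall accuracy
    (fraction of samples whose class is predicted exactly) is reported
    alongside the pooled metrics.
    """
    y = np.asarray(true_classes).astype(int)
    p = np.asarray(predicted_classes).astype(int)
    if y.shape != p.shape:
        raise ValueError("aligned vectors required")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    for arr in (y, p):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"class labels must lie in 0..{n_classes - 1}")
    tp = fp = tn = fn = 0
    for k in range(n_classes):
        t = y == k
        q = p == k
        tp += int(np.sum(t & q))
        fp += int(np.sum(~t & q))
        tn += int(np.sum(~t & ~q))
        fn += int(np.sum(t & ~q))
    pooled = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    record = {
        "accuracy": _safe_ratio(int(np.sum(y == p)), len(y)),
        "micro_accuracy": _safe_ratio(pooled.tp + pooled.tn, pooled.total),
        "micro_sensitivity": _safe_ratio(pooled.tp, pooled.tp + pooled.fn),
        "micro_specificity": _safe_ratio(pooled.tn, pooled.tn + pooled.fp),
        "micro_precision": _safe_ratio(pooled.tp, pooled.tp + pooled.fp),
    }
    return record


def micro_auc(true_classes, probabilities) -> float | None:
    """Pooled one-vs-rest rank AUC over all class columns (micro-AUC)."""
    y = np.asarray(true_classes).astype(int)
    prob = np.asarray(probabilities, dtype=float)
    labels = []
    scores = []
    for k in range(prob.shape[1]):
        labels.append((y == k).astype(int))
        scores.append(prob[:, k])
    return rank_auc(np.concatenate(labels), np.concatenate(scores))


def regression_metrics(y_true, y_pred) -> dict:
    """MSE, MAE and the coefficient of determination R^2.

    R^2 is undefined (``None``) when ``y_true`` is constant.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("aligned 1-D vectors required")
    if len(y_true) < 2:
        raise ValueError("need at least 2 samples")
    resid = y_true - y_pred
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    return {
        "mse": float(np.mean(resid ** 2)),
        "mae": float(np.mean(np.abs(resid))),
        "r2": (1.0 - ss_res / ss_tot) if ss_tot > 0 else None,
    }


@dataclass
class RepeatedEvalReport:
    """Per-iteration metric records plus their aggregates.

    ``records`` holds dicts with iteration index, seed, metric name and
    value; ``aggregates`` maps each metric to the arithmetic mean of its
    defined per-iteration values, ``dispersion`` to their standard
    deviation. Iterations with degenerate splits are listed in
    ``failed_iterations`` and excluded.
    """

    task: str
    n_iterations: int
    records: list = field(default_factory=list)
    aggregates: dict = field(default_factory=dict)
    dispersion: dict = field(default_factory=dict)
    failed_iterations: list = field(default_factory=list)

    def finalize(self):
        by_metric: dict[str, list[float]] = {}
        for rec in self.records:
            if rec["value"] is not None:
                by_metric.setdefault(rec["metric"], []).append(rec["value"])
        self.aggregates = {m: float(np.mean(v)) for m, v in by_metric.items()}
        self.dispersion = {m: float(np.std(v)) for m, v in by_metric.items()}
        return self

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(payload)
        return payload

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def _score(estimator, X_test, y_test, task: str) -> dict:
    if task == "binary":
        y_pred = estimator.predict(X_test)
        counts = confusion_counts(y_test, y_pred)
        scores = None
        if hasattr(estimator, "predict_proba"):
            scores = estimator.predict_proba(X_test)[:, 1]
        return binary_metrics(counts, scores=scores, y_true=y_test)
    if task == "multiclass":
        y_pred = estimator.predict(X_test)
        classes = np.unique(y_test)
        n_classes = int(max(classes.max(), np.max(y_pred)) + 1)
        record = micro_metrics(y_test, y_pred, n_classes)
        if hasattr(estimator, "predict_proba"):
            record["micro_auc"] = micro_auc(y_test, estimator.predict_proba(X_test))
        return record
    return regression_metrics(y_test, estimator.predict(X_test))


def _seeded_clone(estimator, seed: int):
    est = clone(estimator)
    if "random_state" in est.get_params():
        est.set_params(random_state=seed)
    return est


def repeated_holdout(
    estimator,
    X,
    y,
    task: str,
    n_iter: int = 30,
    test_fraction: float = 0.2,
    base_seed: int = 0,
    cv_folds: int | None = None,
) -> RepeatedEvalReport:
    """Repeat shuffle -> 80/20 split (at the mixture level) -> fit -> score.

    Iteration ``i`` uses seed ``base_seed + i`` for the shuffle and, when
    the learner accepts one, for its ``random_state``. With ``cv_folds``
    set, a k-fold cross-validation on the training portion is reported
    separately under ``cv_``-prefixed metric names. Iterations whose test
    split ends up single-class (classification) are flagged and excluded.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if len(X) == 0:
        raise ValueError("empty dataset")
    report = RepeatedEvalReport(task=task, n_iterations=n_iter)
    for i in range(n_iter):
        seed = base_seed + i
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=test_fraction, shuffle=True, random_state=seed
        )
        if task in ("binary", "multiclass") and (
            len(np.unique(y_te)) < 2 or len(np.unique(y_tr)) < 2
        ):
            report.failed_iterations.append({"iteration": i, "reason": "degenerate split"})
            continue
        est = _seeded_clone(estimator, seed)
        est.fit(X_tr, y_tr)
        for metric, value in _score(est, X_te, y_te, task).items():
            report.records.append(
                {"iteration": i, "seed": seed, "metric": metric, "value": value}
            )
        if cv_folds:
            for metric, value in _cross_validate(est, X_tr, y_tr, task, cv_folds, seed).items():
                report.records.append(
                    {"iteration": i, "seed": seed, "metric": f"cv_{metric}", "value": value}
                )
    return report.finalize()


def _cross_validate(estimator, X, y, task, folds, seed) -> dict:
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_records: dict[str, list[float]] = {}
    for tr_idx, te_idx in kf.split(X):
        if task in ("binary", "multiclass") and len(np.unique(y[te_idx])) < 2:
            continue
        est = _seeded_clone(estimator, seed)
        est.fit(X[tr_idx], y[tr_idx])
        for metric, value in _score(est, X[te_idx], y[te_idx], task).items():
            if value is not None:
                fold_records.setdefault(metric, []).append(value)
    return {m: float(np.mean(v)) for m, v in fold_records.items()}


def check_disjoint(train_chem_ids, test_chem_ids) -> None:
    """Raise :class:`LeakageError` listing chemicals on both sides."""
    overlap = set(train_chem_ids) & set(test_chem_ids)
    if overlap:
        raise LeakageError(overlap)


def disjoint_eval(
    estimator,
    X_train,
    y_train,
    X_test,
    y_test,
    train_chem_ids,
    test_chem_ids,
    task: str,
    n_iter: int = 30,
    base_seed: int = 0,
) -> RepeatedEvalReport:
    """Score a fixed compound-disjoint test set.

    The chemical-level disjointness is verified (not assumed) before any
    fitting; repetition varies only the learner seed, so a deterministic
    learner yields zero dispersion.
    """
    check_disjoint(train_chem_ids, test_chem_ids)
    X_train = np.asarray(X_train)
    y_train = np.asarray(y_train)
    X_test = np.asarray(X_test)
    y_test = np.asarray(y_test)
    report = RepeatedEvalReport(task=task, n_iterations=n_iter)
    for i in range(n_iter):
        seed = base_seed + i
        est = _seeded_clone(estimator, seed)
        est.fit(X_train, y_train)
        for metric, value in _score(est, X_test, y_test, task).items():
            report.records.append(
                {"iteration": i, "seed": seed, "metric": metric, "value": value}
            )
    return report.finalize()
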