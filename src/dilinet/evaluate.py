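"""Metrics, baselines, and the multi-seed trial protocol.

AUC-ROC is the Mann–Whitney pair-ranking probability (ties at 0.5), AUC-PR
is non-interpolated average precision, and F1 uses a 0.5 probability
threshold. Trial aggregation reports the per-metric mean and *sample*
standard deviation (n−1 denominator) across seeds, the convention that
reproduces the published five-trial summary.

Baselines (random forest, RBF-kernel SVM, L2 logistic regression) consume
the raw 2,048-bit fingerprints; folding is a network-specific adaptation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn import metrics as _skm
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .model import DiliClassifier, ModelConfig
from .train import TrainConfig, fit, split_dataset

__all__ = ["MetricsRecord", "TrialSummary", "UndefinedMetricError", "auc_roc", "auc_pr",
           "f1_score", "evaluate_model", "run_trials", "summarize_trials", "fit_baseline",
           "benchmark", "BASELINE_PARAMS"]

BASELINE_PARAMS = {
    "RF": {"n_estimators": 500},
    "SVM": {"kernel": "rbf", "C": 1.0, "probability": True},
    "LR": {"C": 1.0, "max_iter": 2000},  # scikit-learn default penalty is L2
}


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given label composition."""


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d arrays")
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError("labels must be binary")
    return scores, labels


@dataclass
class MetricsRecord:
    auc_roc: float
    auc_pr: float
    f1: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrialSummary:
    """Per-seed metric records plus mean and sample SD for each metric."""

    per_trial: list
    seeds: list
    mean: MetricsRecord
    sd: MetricsRecord

    def to_dict(self) -> dict:
        return {"seeds": list(self.seeds),
                "per_trial": [r.to_dict() for r in self.per_trial],
                "mean": self.mean.to_dict(), "sd": self.sd.to_dict()}


def auc_roc(scores, labels) -> float:
    """Probability a random positive outscores a random negative (ties 0.5)."""
    scores, labels = _validate(scores, labels)
    if labels.min() == labels.max():
        raise UndefinedMetricError("AUC-ROC requires both classes present")
    return float(_skm.roc_auc_score(labels, scores))


def auc_pr(scores, labels) -> float:
    """Non-interpolated average precision over descending-score thresholds."""
    scores, labels = _validate(scores, labels)
    if labels.sum() == 0:
        raise UndefinedMetricError("AUC-PR requires at least one positive")
    return float(_skm.average_precision_score(labels, scores))


def f1_score(pred_labels, labels) -> float:
    """Harmonic mean of precision and recall; 0 when there are no true positives."""
    pred, labels = _validate(pred_labels, labels)
    if not np.all(np.isin(pred.astype(int), (0, 1))):
        raise ValueError("predicted labels must be binary")
    return float(_skm.f1_score(labels, pred.astype(int), zero_division=0))


def evaluate_model(model, x_test: np.ndarray, y_test: np.ndarray) -> MetricsRecord:
    """Score a fitted model (anything with ``predict_proba``) on a test set."""
    probs = np.asarray(model.predict_proba(x_test), dtype=np.float64)
    if probs.ndim == 2:  # scikit-learn two-column convention
        probs = probs[:, 1]
    y_test = np.asarray(y_test, dtype=int)
    return MetricsRecord(auc_roc=auc_roc(probs, y_test),
                         auc_pr=auc_pr(probs, y_test),
                         f1=f1_score((probs >= 0.5).astype(int), y_test))


def summarize_trials(records: list, seeds=None) -> TrialSummary:
    """Aggregate per-trial metric records into mean and sample SD (ddof=1)."""
    if len(records) < 2:
        raise ValueError("need at least two trials to aggregate")
    arr = np.array([[r.auc_roc, r.auc_pr, r.f1] for r in records])
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    return TrialSummary(per_trial=list(records),
                        seeds=list(seeds) if seeds is not None else list(range(len(records))),
                        mean=MetricsRecord(*mean), sd=MetricsRecord(*sd))


def run_trials(x: np.ndarray, y: np.ndarray, mcfg: ModelConfig | None = None,
               tcfg: TrainConfig | None = None, seeds=(1, 2, 3, 4, 5)) -> TrialSummary:
    """Independent resplit–retrain–evaluate trials, one per seed."""
    seeds = list(seeds)
    if len(seeds) < 2:
        raise ValueError("need at least two seeds")
    mcfg = mcfg or ModelConfig()
    records = []
    for seed in seeds:
        split = split_dataset(len(y), seed)
        trial_tcfg = TrainConfig(**{**(tcfg or TrainConfig()).to_dict(), "seed": seed})
        model, _ = fit(x, y, split, mcfg, trial_tcfg)
        records.append(evaluate_model(model, x[split.test], y[split.test]))
    return summarize_trials(records, seeds)


def fit_baseline(kind: str, fingerprints: np.ndarray, labels: np.ndarray, seed: int = 0):
    """Fit one of the reference classifiers on raw fingerprint bits.

    Returns a fitted scikit-learn estimator exposing ``predict_proba``.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("baseline training data must contain both classes")
    if kind == "RF":
        clf = RandomForestClassifier(random_state=seed, **BASELINE_PARAMS["RF"])
    elif kind == "SVM":
        clf = SVC(random_state=seed, **BASELINE_PARAMS["SVM"])
    elif kind == "LR":
        clf = LogisticRegression(random_state=seed, **BASELINE_PARAMS["LR"])
    else:
        raise ValueError(f"unknown baseline kind {kind!r} (expected RF, SVM or LR)")
    clf.fit(np.asarray(fingerprints, dtype=np.float64), labels)
    return clf


def benchmark(x_fp: np.ndarray, x_net: np.ndarray, y: np.ndarray, seed: int = 0,
              mcfg: ModelConfig | None = None, tcfg: TrainConfig | None = None) -> dict:
    """Compare the network against RF/SVM/LR on one shared split.

    ``x_fp`` are the raw 2,048-bit fingerprints (baseline input), ``x_net``
    the corresponding network inputs. Returns {method: MetricsRecord}.
    """
    y = np.asarray(y, dtype=int)
    split = split_dataset(len(y), seed)
    dev = np.concatenate([split.train, split.val])
    rows: dict[str, MetricsRecord] = {}
    for kind in ("RF", "SVM", "LR"):
        clf = fit_baseline(kind, x_fp[dev], y[dev], seed=seed)
        rows[kind] = evaluate_model(clf, x_fp[split.test], y[split.test])
    tcfg = TrainConfig(**{**(tcfg or TrainConfig()).to_dict(), "seed": seed})
    model, _ = fit(x_net, y, split, mcfg, tcfg)
    rows["ours"] = evaluate_model(model, x_net[split.test], y[split.test])
    return rows
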