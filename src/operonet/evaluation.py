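"""Classification metrics, ROC/AUROC, imputation and k-fold cross-validation.

Conventions:

* F1 = 2 * precision * recall / (precision + recall); when the denominator
  is zero the score is reported as 0 with a flag rather than NaN, so batch
  summaries never propagate NaN.
* AUROC is the rank statistic (ties count 0.5): the probability that a
  random positive is scored above a random negative.  Hard 0/1 predictions
  are accepted as scores, matching how tools that emit only calls are
  compared.
* Pairs a tool failed to predict are imputed with probability 0.49 and a
  hard non-operon call, so every method is measured on the same universe
  of gene pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

IMPUTED_PROBABILITY = 0.49


class UndefinedMetricError(ValueError):
    """Metric is undefined for the given inputs (e.g. single-class AUROC)."""


@dataclass
class MetricsReport:
    recall: float
    precision: float
    f1: float
    accuracy: float
    tp: int
    fp: int
    tn: int
    fn: int
    auroc: Optional[float] = None
    roc_points: Optional[list[tuple[float, float]]] = None
    n_imputed: int = 0
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "recall": self.recall, "precision": self.precision,
            "f1": self.f1, "accuracy": self.accuracy,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "auroc": self.auroc, "n_imputed": self.n_imputed,
            "flags": list(self.flags),
        }


def _validate(labels, probabilities):
    labels = np.asarray(labels)
    probabilities = np.asarray(probabilities, dtype=float)
    if labels.shape != probabilities.shape:
        raise ValueError("labels and probabilities must have equal length")
    if labels.size == 0:
        raise ValueError("need at least one instance")
    if not np.isin(labels, [0, 1]).all():
        raise ValueError("labels must be 0/1")
    return labels.astype(int), probabilities


def confusion_and_scores(
    labels: Sequence[int],
    probabilities: Sequence[float],
    threshold: float = 0.5,
) -> MetricsReport:
    """Confusion counts and threshold metrics (no ROC)."""
    labels, probabilities = _validate(labels, probabilities)
    pred = (probabilities >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    flags = []
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    if tp + fn == 0:
        flags.append("no_positive_labels")
    if tp + fp == 0:
        precision = 0.0
        flags.append("no_predicted_positives")
    else:
        precision = tp / (tp + fp)
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0
        flags.append("f1_undefined")
    accuracy = (tp + tn) / labels.size
    return MetricsReport(recall=recall, precision=precision, f1=f1,
                         accuracy=accuracy, tp=tp, fp=fp, tn=tn, fn=fn,
                         flags=flags)


def auroc(
    labels: Sequence[int], probabilities: Sequence[float]
) -> tuple[float, list[tuple[float, float]]]:
    """Rank-based AUROC (ties 0.5) plus ROC points from (0,0) to (1,1).

    Scores may be continuous probabilities or hard 0/1 calls.
    """
    labels, probabilities = _validate(labels, probabilities)
    if np.unique(labels).size < 2:
        raise UndefinedMetricError("AUROC needs both classes present")
    value = float(roc_auc_score(labels, probabilities))
    fpr, tpr, _ = roc_curve(labels, probabilities)
    points = list(zip(fpr.tolist(), tpr.tolist()))
    return value, points


def impute_missing(
    predictions: Mapping[str, float],
    universe: Sequence[str],
) -> tuple[dict[str, float], int]:
    """Complete a pair->probability map over a universe of pair ids.

    Pairs absent from ``predictions`` receive probability exactly 0.49 —
    just under the decision boundary, so an absent prediction counts as a
    non-operon call while barely perturbing rank metrics.  Returns the
    completed map and the number of imputed pairs.
    """
    complete = {}
    n_imputed = 0
    for pair_id in universe:
        if pair_id in predictions:
            complete[pair_id] = float(predictions[pair_id])
        else:
            complete[pair_id] = IMPUTED_PROBABILITY
            n_imputed += 1
    return complete, n_imputed


def evaluate_predictions(
    labels: Sequence[int],
    probabilities: Sequence[float],
    threshold: float = 0.5,
    with_roc: bool = True,
    n_imputed: int = 0,
) -> MetricsReport:
    """Full metrics report; AUROC omitted (None) when only one class."""
    report = confusion_and_scores(labels, probabilities, threshold=threshold)
    report.n_imputed = n_imputed
    if with_roc:
        try:
            report.auroc, report.roc_points = auroc(labels, probabilities)
        except UndefinedMetricError:
            report.flags.append("auroc_undefined")
    return report


def mean_and_ci(values: Sequence[float], level: float = 0.90) -> dict:
    """Mean and t-interval over folds: mean +/- t(1-(1-level)/2, k-1)*sd/sqrt(k)."""
    values = np.asarray(values, dtype=float)
    k = values.size
    mean = float(values.mean())
    if k < 2:
        return {"mean": mean, "ci_low": mean, "ci_high": mean}
    half = float(
        stats.t.ppf(1 - (1 - level) / 2, k - 1) * values.std(ddof=1) / np.sqrt(k)
    )
    return {"mean": mean, "ci_low": mean - half, "ci_high": mean + half}


def kfold_cv(
    tensors: np.ndarray,
    labels: np.ndarray,
    config,
    k: int = 10,
    seed: int = 0,
) -> dict:
    """Stratified k-fold cross-validation of the ensemble classifier.

    Trains one ensemble per fold on the remaining folds and evaluates on
    the held-out fold.  Returns per-fold reports plus the mean and 90%
    confidence interval per metric, the format used for cross-validated
    summaries.
    """
    from .model import OperonModel  # deferred: avoid import cycle

    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} items; cannot stratify into "
            f"{k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_reports = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(tensors, labels)):
        model = OperonModel(tensors[train_idx], labels[train_idx], config=config)
        results = model.fit()
        probs = results.predict_proba(tensors[test_idx])
        report = evaluate_predictions(labels[test_idx], probs,
                                      threshold=config.threshold)
        fold_reports.append(report)
    summary = {
        metric: mean_and_ci([getattr(r, metric) for r in fold_reports])
        for metric in ("recall", "precision", "f1", "accuracy", "auroc")
    }
    return {"folds": fold_reports, "summary": summary, "k": k}


def grid_search(
    tensors: np.ndarray,
    labels: np.ndarray,
    base_config,
    grid: Mapping[str, Sequence],
    k: int = 10,
    seed: int = 0,
    metric: str = "auroc",
) -> list[dict]:
    """Plain loop over a hyperparameter grid, ranked by cross-validated metric."""
    import itertools
    from dataclasses import replace

    keys = list(grid)
    results = []
    for combo in itertools.product(*(grid[key] for key in keys)):
        config = replace(base_config, **dict(zip(keys, combo)))
        cv = kfold_cv(tensors, labels, config, k=k, seed=seed)
        results.append({
            "params": dict(zip(keys, combo)),
            "summary": cv["summary"],
            "score": cv["summary"][metric]["mean"],
        })
    results.sort(key=lambda r: -r["score"])
    return results
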