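"""Evaluation harness: stratified folds, drug-anchored splits, and the
one-vs-rest metric suite.

Every metric reduces the 4-class problem to four binary problems.  For a
class c, TP are true-c pairs predicted c, FN true-c predicted otherwise,
FP other-class pairs predicted c, TN the rest.  Per class we report
accuracy, precision, sensitivity (recall), specificity,
F1 = 2*precision*recall / (precision + recall) and
balanced accuracy = (sensitivity + specificity) / 2.  Aggregates are the
plain macro mean over the four classes and the frequency-weighted macro
(class weight = class count / total).  ROC-AUC is computed one-vs-rest
from the soft-voted probabilities by pairwise concordance (ties count
half), which equals the Mann-Whitney statistic.

`macro_recall` (the mean of the four sensitivities, i.e. multiclass
balanced accuracy in the sklearn sense) is reported alongside: its
chance level for four classes is 0.25, which makes it the right anchor
for signal-recovery checks on synthetic data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .grades import GRADE_ORDER, GradeLabel, N_GRADES
from .records import LabeledPair

logger = logging.getLogger(__name__)

PER_CLASS_METRICS = (
    "accuracy",
    "precision",
    "sensitivity",
    "specificity",
    "f1",
    "balanced_accuracy",
)


def stratified_kfold(y, k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold index (0..k-1) per sample, preserving class proportions.

    Per-class seeded shuffle followed by round-robin assignment with a
    global rotating start, so per-fold class counts are within one pair
    of perfect proportionality and fold sizes differ by at most one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray([int(v) for v in y])
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    assigned = 0
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        if len(idx) < k:
            logger.warning(
                "class %d has %d < k=%d pairs; folds will not all contain it",
                cls, len(idx), k,
            )
        for j, sample in enumerate(idx):
            folds[sample] = (assigned + j) % k
        assigned += len(idx)
    return folds


def drug_anchored_split(
    pairs: list[LabeledPair], holdout_ids: set[str]
) -> tuple[list[LabeledPair], list[LabeledPair]]:
    """Hold out every pair whose ARV is in `holdout_ids` (unseen-drug test)."""
    holdout_ids = set(holdout_ids)
    test = [p for p in pairs if p.arv_id in holdout_ids]
    train = [p for p in pairs if p.arv_id not in holdout_ids]
    if not test:
        warnings.warn("drug-anchored split produced an empty test set")
    return train, test


def confusion(true, pred) -> np.ndarray:
    """4x4 count matrix, rows = true grade, columns = predicted grade."""
    true = np.asarray([int(v) for v in true])
    pred = np.asarray([int(v) for v in pred])
    if true.shape != pred.shape:
        raise ValueError("true and predicted label lists differ in length")
    cm = np.zeros((N_GRADES, N_GRADES), dtype=int)
    np.add.at(cm, (true, pred), 1)
    return cm


def normalize_confusion(cm: np.ndarray) -> np.ndarray:
    """Row-normalized (per true class) proportions; zero rows stay zero."""
    cm = np.asarray(cm, dtype=float)
    sums = cm.sum(axis=1, keepdims=True)
    out = np.zeros_like(cm)
    nz = sums[:, 0] > 0
    out[nz] = cm[nz] / sums[nz]
    return out


def per_class_metrics(cm: np.ndarray) -> dict[GradeLabel, dict[str, float]]:
    """One-vs-rest metric block per grade from a 4x4 confusion matrix.

    0/0 conventions: precision, sensitivity and F1 are 0 when their
    denominator is 0 (no predicted / no true positives).
    """
    cm = np.asarray(cm)
    total = cm.sum()
    out: dict[GradeLabel, dict[str, float]] = {}
    for grade in GRADE_ORDER:
        c = int(grade)
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        precision = tp / (tp + fp) if tp + fp else 0.0
        sensitivity = tp / (tp + fn) if tp + fn else 0.0
        specificity = tn / (tn + fp) if tn + fp else 0.0
        accuracy = (tp + tn) / total if total else 0.0
        f1 = (
            2 * precision * sensitivity / (precision + sensitivity)
            if precision + sensitivity
            else 0.0
        )
        out[grade] = {
            "accuracy": float(accuracy),
            "precision": float(precision),
            "sensitivity": float(sensitivity),
            "specificity": float(specificity),
            "f1": float(f1),
            "balanced_accuracy": (sensitivity + specificity) / 2,
        }
    return out


def weighted_macro(
    per_class: dict[GradeLabel, dict[str, float]],
    counts: dict[GradeLabel, int],
) -> dict[str, dict[str, float]]:
    """Plain macro (mean over the 4 classes) and frequency-weighted macro
    (class weight = count / total) of every per-class metric."""
    total = sum(counts.get(g, 0) for g in GRADE_ORDER)
    if total == 0:
        raise ValueError("no evaluated pairs")
    weights = {g: counts.get(g, 0) / total for g in GRADE_ORDER}
    macro, weighted = {}, {}
    metrics = [
        m for m in PER_CLASS_METRICS
        if all(m in per_class[g] for g in GRADE_ORDER)
    ]
    for metric in metrics:
        values = [per_class[g][metric] for g in GRADE_ORDER]
        macro[metric] = float(np.mean(values))
        weighted[metric] = float(
            sum(weights[g] * per_class[g][metric] for g in GRADE_ORDER)
        )
    return {
        "macro": macro,
        "weighted": weighted,
        "class_weights": {g.display: weights[g] for g in GRADE_ORDER},
    }


def roc_auc_ovr(true, probabilities) -> dict[GradeLabel, dict]:
    """Per-class one-vs-rest ROC curve and AUC from voted probabilities.

    AUC is the pairwise concordance P(score_pos > score_neg) with ties
    counting one half (Mann-Whitney).  A class absent from the truth (or
    covering it entirely) has no defined AUC and is reported as None.
    """
    true = np.asarray([int(v) for v in true])
    probs = np.asarray(probabilities, dtype=float)
    if probs.ndim != 2 or probs.shape != (len(true), N_GRADES):
        raise ValueError(f"expected ({len(true)}, {N_GRADES}) probabilities")
    if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probabilities are not normalized")
    out: dict[GradeLabel, dict] = {}
    for grade in GRADE_ORDER:
        scores = probs[:, int(grade)]
        pos = true == int(grade)
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            out[grade] = {"auc": None, "fpr": None, "tpr": None, "thresholds": None}
            continue
        ranks = rankdata(scores)  # average ranks: ties count 1/2
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        fpr, tpr, thresholds = _roc_points(scores, pos)
        out[grade] = {
            "auc": float(auc),
            "fpr": fpr,
            "tpr": tpr,
            "thresholds": thresholds,
        }
    return out


def _roc_points(scores, pos):
    """ROC step points at every distinct threshold, descending."""
    order = np.argsort(-scores, kind="stable")
    scores_sorted = scores[order]
    pos_sorted = pos[order].astype(float)
    distinct = np.r_[np.flatnonzero(np.diff(scores_sorted)), len(scores_sorted) - 1]
    tps = np.cumsum(pos_sorted)[distinct]
    fps = (distinct + 1) - tps
    tpr = np.r_[0.0, tps / pos.sum()]
    fpr = np.r_[0.0, fps / (~pos).sum()]
    thresholds = np.r_[np.inf, scores_sorted[distinct]]
    return fpr, tpr, thresholds


@dataclass
class MetricsReport:
    """Per-class one-vs-rest metrics plus macro / weighted-macro aggregates."""

    counts: dict[GradeLabel, int]
    confusion_matrix: np.ndarray
    per_class: dict[GradeLabel, dict[str, float]]
    macro: dict[str, float]
    weighted: dict[str, float]
    class_weights: dict[str, float]
    auc: dict[GradeLabel, float | None]
    macro_recall: float  # multiclass balanced accuracy; chance = 1/4

    def to_dict(self) -> dict:
        return {
            "counts": {g.display: self.counts.get(g, 0) for g in GRADE_ORDER},
            "confusion_matrix": self.confusion_matrix.tolist(),
            "normalized_confusion_matrix": normalize_confusion(
                self.confusion_matrix
            ).tolist(),
            "per_class": {
                g.display: self.per_class[g] for g in GRADE_ORDER
            },
            "macro": self.macro,
            "weighted": self.weighted,
            "class_weights": self.class_weights,
            "auc": {
                g.display: self.auc.get(g) for g in GRADE_ORDER
            },
            "macro_recall": self.macro_recall,
        }


def evaluate_predictions(true, pred, probabilities=None) -> MetricsReport:
    """Full metric report for one set of predictions."""
    true = np.asarray([int(v) for v in true])
    pred = np.asarray([int(v) for v in pred])
    cm = confusion(true, pred)
    per_class = per_class_metrics(cm)
    counts = {g: int(np.sum(true == int(g))) for g in GRADE_ORDER}
    aggregates = weighted_macro(per_class, counts)
    if probabilities is not None:
        auc = {
            g: block["auc"] for g, block in roc_auc_ovr(true, probabilities).items()
        }
    else:
        auc = {g: None for g in GRADE_ORDER}
    present = [g for g in GRADE_ORDER if counts[g] > 0]
    macro_recall = float(
        np.mean([per_class[g]["sensitivity"] for g in present])
    )
    return MetricsReport(
        counts=counts,
        confusion_matrix=cm,
        per_class=per_class,
        macro=aggregates["macro"],
        weighted=aggregates["weighted"],
        class_weights=aggregates["class_weights"],
        auc=auc,
        macro_recall=macro_recall,
    )


def crossval(
    drugs,
    pairs: list[LabeledPair],
    config,
    network=None,
) -> dict:
    """Stratified k-fold cross-validation of the full pipeline.

    Featurizes once over the whole drug universe, then for each fold
    trains a fresh ensemble on the other k-1 folds and evaluates on the
    held fold.  Returns per-fold reports plus a mean +/- sd summary of
    the weighted-macro metrics and macro recall.
    """
    from .ensemble import EnsembleDDIClassifier
    from .features import make_featurizer

    featurizer = make_featurizer(
        config.featurizer_backend, drugs, config.fingerprint_radius,
        config.fingerprint_bits,
    ).fit()
    X = featurizer.transform([(p.arv_id, p.comed_id) for p in pairs])
    y = np.array([int(p.grade) for p in pairs])
    folds = stratified_kfold(y, config.cv_folds, config.seed)

    fold_reports = []
    for fold in range(config.cv_folds):
        fold_seed = config.seed + 1000 * (fold + 1)
        mask = folds == fold
        clf = EnsembleDDIClassifier(
            n_members=config.ensemble_size,
            network=network or config.network_preset,
            random_state=fold_seed,
        ).fit(X[~mask], y[~mask])
        probs = clf.predict_proba(X[mask])
        report = evaluate_predictions(y[mask], clf.predict(X[mask]), probs)
        entry = report.to_dict()
        entry["fold"] = fold
        entry["seed"] = fold_seed
        entry["n_train"] = int((~mask).sum())
        entry["n_test"] = int(mask.sum())
        fold_reports.append(entry)
        logger.info(
            "fold %d: weighted balanced accuracy %.3f, macro recall %.3f",
            fold,
            entry["weighted"]["balanced_accuracy"],
            entry["macro_recall"],
        )

    summary = {}
    for metric in PER_CLASS_METRICS:
        values = [r["weighted"][metric] for r in fold_reports]
        summary[f"weighted_{metric}"] = {
            "mean": float(np.mean(values)),
            "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
        }
    recalls = [r["macro_recall"] for r in fold_reports]
    summary["macro_recall"] = {
        "mean": float(np.mean(recalls)),
        "sd": float(np.std(recalls, ddof=1)) if len(recalls) > 1 else 0.0,
    }
    return {"folds": fold_reports, "summary": summary}
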