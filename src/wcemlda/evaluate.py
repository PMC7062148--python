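"""End-to-end evaluation: metrics, cross-validation, binary task reductions.

The evaluation protocol keeps the pixel-labeled bank images separate from
the image-level evaluation set: the LDA bank is built once, features are
extracted once, and only the cascade (including its per-machine feature
standardization and hyperparameter search) is re-trained inside each
cross-validation fold, so no information from a test fold leaks into
training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .cascade import DEFAULT_C_GRID, DEFAULT_SIGMA_GRID, grid_search, train_binary
from .features import featurize_dataset
from .lda import ModelBank
from .model import HierarchicalSVC
from .synthetic import LabeledImage

CLASS_ORDER = ("B", "U", "T", "N")


@dataclass
class PipelineConfig:
    """Run configuration for feature extraction and cascade training."""

    colorspace: str = "RGB"
    pdf_family: str = "normal"
    feature_variant: str = "pdf"  # pdf | count | stat | whole_image
    C_grid: tuple = DEFAULT_C_GRID
    sigma_grid: tuple = DEFAULT_SIGMA_GRID
    svm_folds: int = 3  # inner folds for per-machine grid search
    cv_folds: int = 10  # outer evaluation folds

    def to_dict(self) -> dict:
        d = asdict(self)
        d["C_grid"] = list(self.C_grid)
        d["sigma_grid"] = list(self.sigma_grid)
        return d


@dataclass
class EvaluationReport:
    """Pooled multi-class cross-validation results.

    Percentages are on [0, 100]; macro metrics are unweighted means over
    the classes present in the truth vector.  Per-class entries for classes
    absent from the truth are ``None``.
    """

    confusion_matrix: list[list[int]]  # rows = truth, CLASS_ORDER
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class: dict[str, dict[str, float | None]]
    roc: dict[str, list[list[float]]] = field(default_factory=dict)
    fold_assignments: dict[str, int] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.confusion_matrix, index=list(CLASS_ORDER), columns=list(CLASS_ORDER)
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        return cls(**json.loads(text))


@dataclass
class BinaryReport:
    """Two-class (disease vs normal) results.

    Undefined denominators (e.g. specificity on an all-diseased set) are
    reported as ``None``, never as 0.
    """

    sensitivity: float | None
    specificity: float | None
    accuracy: float
    tp: int
    fn: int
    tn: int
    fp: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def compute_metrics(truth, predicted) -> EvaluationReport:
    """Confusion matrix, accuracy and macro precision/recall/F1 (percent)."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if len(truth) != len(predicted) or len(truth) == 0:
        raise ValueError(
            f"truth and predicted must have equal nonzero lengths "
            f"({len(truth)} vs {len(predicted)})"
        )
    cm = np.zeros((4, 4), dtype=int)
    index = {c: i for i, c in enumerate(CLASS_ORDER)}
    for t, p in zip(truth, predicted):
        cm[index[t], index[p]] += 1
    accuracy = 100.0 * np.trace(cm) / cm.sum()
    per_class: dict[str, dict[str, float | None]] = {}
    precisions, recalls, f1s = [], [], []
    for c in CLASS_ORDER:
        i = index[c]
        support = cm[i].sum()
        if support == 0:
            per_class[c] = {"precision": None, "recall": None, "f1": None, "support": 0}
            continue
        tp = cm[i, i]
        predicted_c = cm[:, i].sum()
        precision = 100.0 * tp / predicted_c if predicted_c else 0.0
        recall = 100.0 * tp / support
        f1 = (
            2 * precision * recall / (precision + recall)
            if (precision + recall) > 0
            else 0.0
        )
        per_class[c] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": int(support),
        }
        precisions.append(precision)
        recalls.append(recall)
        f1s.append(f1)
    return EvaluationReport(
        confusion_matrix=cm.tolist(),
        accuracy=float(accuracy),
        macro_precision=float(np.mean(precisions)),
        macro_recall=float(np.mean(recalls)),
        macro_f1=float(np.mean(f1s)),
        per_class=per_class,
    )


def roc_points(scores: dict[str, np.ndarray], truth) -> dict[str, list[list[float]]]:
    """One-vs-rest ROC point lists per class from decision-value sweeps."""
    truth = np.asarray(truth)
    out: dict[str, list[list[float]]] = {}
    for c, s in scores.items():
        y = (truth == c).astype(int)
        if y.sum() == 0 or y.sum() == len(y):
            out[c] = []
            continue
        fpr, tpr, _ = roc_curve(y, np.asarray(s, dtype=float))
        out[c] = [[float(f), float(t)] for f, t in zip(fpr, tpr)]
    return out


def cross_validate(
    images: list[LabeledImage],
    bank: ModelBank,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified k-fold evaluation of the full pipeline.

    The bank is fixed (built beforehand from a disjoint pixel-labeled set)
    and features are extracted once; the cascade is trained per fold on the
    training split only and all out-of-fold predictions are pooled.
    ``folds == n`` requests leave-one-out.
    """
    config = config or PipelineConfig()
    x, labels, ids, _ = featurize_dataset(
        images, bank, config.feature_variant, config.pdf_family, config.colorspace
    )
    n = len(labels)
    folds = config.cv_folds
    if folds == n:
        splitter = KFold(n_splits=n)
        split = splitter.split(x)
    else:
        counts = pd.Series(labels).value_counts()
        small = counts[counts < folds]
        if not small.empty:
            raise ValueError(
                f"classes smaller than the fold count {folds}: "
                f"{dict(small)}"
            )
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(x, labels)

    predicted = np.empty(n, dtype=object)
    scores = {c: np.zeros(n) for c in CLASS_ORDER}
    fold_of = {}
    for fold, (train_idx, test_idx) in enumerate(split):
        results = HierarchicalSVC(x[train_idx], labels[train_idx]).fit(
            config.C_grid, config.sigma_grid, folds=config.svm_folds, seed=seed + fold
        )
        predicted[test_idx] = results.predict(x[test_idx])
        fold_scores = results.decision_scores(x[test_idx])
        for c in CLASS_ORDER:
            scores[c][test_idx] = fold_scores[c]
        for i in test_idx:
            fold_of[ids[i]] = fold
    report = compute_metrics(labels, predicted.astype(str))
    report.roc = roc_points(scores, labels)
    report.fold_assignments = fold_of
    report.config = config.to_dict()
    return report


def binary_report(truth_positive: np.ndarray, pred_positive: np.ndarray) -> BinaryReport:
    """Sensitivity / specificity / accuracy from boolean truth/prediction."""
    t = np.asarray(truth_positive, dtype=bool)
    p = np.asarray(pred_positive, dtype=bool)
    tp = int((t & p).sum())
    fn = int((t & ~p).sum())
    tn = int((~t & ~p).sum())
    fp = int((~t & p).sum())
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else None
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else None
    acc = 100.0 * (tp + tn) / len(t)
    return BinaryReport(
        sensitivity=sens, specificity=spec, accuracy=acc, tp=tp, fn=fn, tn=tn, fp=fp
    )


def run_binary_task(
    images: list[LabeledImage],
    bank: ModelBank,
    task: str = "B",
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> BinaryReport:
    """Single-disease (or any-disease) vs normal reduction of the pipeline.

    For a single-disease task the bank is restricted to that disease's
    models and only a level-1 style binary machine is trained; evaluation
    is stratified k-fold with pooled out-of-fold predictions.
    """
    config = config or PipelineConfig()
    if task in ("B", "U", "T"):
        sub_bank = bank.restrict(task)
        if sub_bank.M == 0:
            raise ValueError(f"bank contains no models for disease {task!r}")
        subset = [img for img in images if img.label in (task, "N")]
        positive = {task}
    elif task == "diseased":
        sub_bank = bank
        subset = list(images)
        positive = {"B", "U", "T"}
    else:
        raise ValueError(f"unknown task {task!r}; expected B, U, T or 'diseased'")
    labels = np.array([img.label for img in subset])
    if not any(l in positive for l in labels) or not any(l == "N" for l in labels):
        raise ValueError(f"task {task!r} requires both task classes in the dataset")
    x, _, _, _ = featurize_dataset(
        subset, sub_bank, config.feature_variant, config.pdf_family, config.colorspace
    )
    y = np.where(np.isin(labels, sorted(positive)), 1, -1)
    folds = min(config.cv_folds, int(min(np.bincount((y + 1) // 2))))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.zeros(len(y), dtype=int)
    for fold, (train_idx, test_idx) in enumerate(skf.split(x, y)):
        C, sigma, _ = grid_search(
            x[train_idx], y[train_idx], config.C_grid, config.sigma_grid,
            folds=config.svm_folds, seed=seed + fold,
        )
        machine = train_binary(x[train_idx], y[train_idx], C, sigma, name=f"{task}|N")
        pred[test_idx] = np.where(machine.decision_values(x[test_idx]) > 0, 1, -1)
    return binary_report(y == 1, pred == 1)
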