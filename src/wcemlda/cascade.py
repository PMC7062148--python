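"""Hierarchical cascade of binary RBF-SVM machines.

Four-class WCE image classification (bleeding B, ulcer U, tumor T,
normal N) is heavily imbalanced -- normal frames dominate -- so instead of
one multiclass machine the decision is staged:

* level 1: a gate machine ``N|~N`` separates normal from diseased;
* level 2: three one-vs-rest disease machines ``B|~B``, ``T|~T``, ``U|~U``
  (trained on diseased images only);
* level 3: pairwise tie-break machines ``B|T``, ``B|U``, ``T|U`` consulted
  only when exactly two level-2 machines claim the image.

Exactly seven machines; no input ever consults more than five.  When zero
or all three level-2 machines fire, the disease with the largest signed
decision value wins (margin fallback -- uses only values already computed,
so the five-machine bound holds).

Each machine is a soft-margin SVM with Gaussian RBF kernel
``K(x, z) = exp(-||x - z||^2 / (2 sigma^2))`` on features standardized with
that machine's own training statistics.  Hyperparameters (C, sigma) are
chosen per machine by stratified k-fold grid search over
C, sigma in {2^-2, 2^-1, ..., 2^8} by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

#: canonical machine order used in serialization and summary tables
MACHINE_NAMES = ("N|~N", "B|~B", "T|~T", "U|~U", "B|T", "B|U", "T|U")

DEFAULT_C_GRID = tuple(2.0**k for k in range(-2, 9))
DEFAULT_SIGMA_GRID = tuple(2.0**k for k in range(-2, 9))

CLASSES = ("B", "U", "T", "N")
_PAIR_MACHINE = {
    frozenset("BT"): "B|T",
    frozenset("BU"): "B|U",
    frozenset("TU"): "T|U",
}


@dataclass
class BinaryMachine:
    """One trained binary RBF-SVM with per-machine standardization.

    The decision value is ``decision_function`` of the underlying SVM with
    the positive (first-named) class mapped to +1; a value of exactly zero
    is resolved to the negative class.
    """

    name: str
    positive_label: str
    negative_label: str
    C: float
    sigma: float
    scaler_mean: np.ndarray = field(repr=False, default=None)
    scaler_scale: np.ndarray = field(repr=False, default=None)
    svc: SVC = field(repr=False, default=None)

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.scaler_mean) / self.scaler_scale

    def decision_values(self, x: np.ndarray) -> np.ndarray:
        """Signed decision values for an (n, d) feature matrix."""
        return self.svc.decision_function(self._standardize(np.atleast_2d(x)))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predicted labels; zero decision values go to the negative class."""
        d = self.decision_values(x)
        return np.where(d > 0, self.positive_label, self.negative_label)


def train_binary(
    features: np.ndarray,
    labels: np.ndarray,
    C: float,
    sigma: float,
    name: str = "binary",
    positive_label: str = "+1",
    negative_label: str = "-1",
) -> BinaryMachine:
    """Train one soft-margin RBF-SVM on +/-1 labels.

    Features are standardized to zero mean / unit scale using the training
    statistics, which are stored in the machine.  Deterministic given a
    fixed input order.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 2:
        x = x.reshape(len(y), -1)
    signs = np.unique(y)
    if len(signs) < 2:
        raise ValueError(f"machine {name!r}: training data contains a single class")
    if not np.isfinite(x).all():
        raise ValueError(f"machine {name!r}: non-finite feature values")
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    xs = (x - mean) / scale
    gamma = 1.0 / (2.0 * sigma**2)
    svc = SVC(C=C, kernel="rbf", gamma=gamma)
    # fit on {0, 1} so decision_function > 0 always means the positive class
    svc.fit(xs, (np.asarray(y) == 1).astype(int))
    machine = BinaryMachine(
        name=name,
        positive_label=positive_label,
        negative_label=negative_label,
        C=C,
        sigma=sigma,
        scaler_mean=mean,
        scaler_scale=scale,
        svc=svc,
    )
    return machine


def _binary_cv_accuracy(
    x: np.ndarray, y: np.ndarray, C: float, sigma: float, folds: int, seed: int
) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, test_idx in skf.split(x, y):
        if len(np.unique(y[train_idx])) < 2:
            continue
        m = train_binary(x[train_idx], y[train_idx], C, sigma)
        d = m.decision_values(x[test_idx])
        pred = np.where(d > 0, 1, -1)
        correct += int((pred == y[test_idx]).sum())
    return correct / len(y)


def grid_search(
    features: np.ndarray,
    labels: np.ndarray,
    C_grid=DEFAULT_C_GRID,
    sigma_grid=DEFAULT_SIGMA_GRID,
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Pick (C, sigma) maximizing mean stratified k-fold accuracy.

    Ties are broken toward smaller C, then smaller sigma.  Returns
    ``(C, sigma, cv_accuracy)``.  Candidates whose training fails are
    skipped.
    """
    if len(C_grid) == 0 or len(sigma_grid) == 0:
        raise ValueError("hyperparameter grids must be nonempty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    # encode to +/-1 for internal CV
    uniq = np.unique(y)
    if len(uniq) != 2:
        raise ValueError(f"grid_search needs exactly two classes, got {list(uniq)}")
    y_pm = np.where(y == uniq[1], 1, -1)
    folds = min(folds, int(min(np.bincount((y_pm + 1) // 2))))
    if folds < 2:
        raise ValueError("each class needs at least 2 members for cross-validation")
    best = None
    for C in sorted(C_grid):
        for sigma in sorted(sigma_grid):
            try:
                acc = _binary_cv_accuracy(x, y_pm, C, sigma, folds, seed)
            except ValueError:
                continue
            if best is None or acc > best[2]:
                best = (C, sigma, acc)
    if best is None:
        raise ValueError("no trainable (C, sigma) candidate in the grids")
    return best


def route(
    gate_is_normal: bool,
    level2: dict[str, float],
    pairwise: dict[str, float] | None = None,
) -> tuple[str, list[str]]:
    """Pure routing logic of the cascade; also used for path enumeration.

    Parameters
    ----------
    gate_is_normal
        Whether the gate machine's decision value favors normal.
    level2
        Signed decision values of the B, T, U one-vs-rest machines
        (positive = claims the disease).
    pairwise
        Signed decision values of the tie-break machines, keyed by machine
        name (``"B|T"`` positive means B).  Only consulted on a two-way tie.

    Returns the predicted label and the audit trail of machines consulted.
    """
    trail = ["N|~N"]
    if gate_is_normal:
        return "N", trail
    order = ("B", "T", "U")
    trail += [f"{d}|~{d}" for d in order]
    positives = [d for d in order if level2[d] > 0]
    if len(positives) == 1:
        return positives[0], trail
    if len(positives) == 2:
        name = _PAIR_MACHINE[frozenset(positives)]
        trail.append(name)
        first, second = name.split("|")
        label = first if (pairwise or {}).get(name, 0.0) > 0 else second
        return label, trail
    # zero or three positives: margin fallback on values already computed
    label = max(order, key=lambda d: level2[d])
    return label, trail


def max_consulted_machines() -> int:
    """Worst-case machines consulted, by exhaustive outcome enumeration."""
    worst = 0
    for gate in (True, False):
        for b in (-1.0, 1.0):
            for t in (-1.0, 1.0):
                for u in (-1.0, 1.0):
                    for pw in (-1.0, 1.0):
                        pairwise = {name: pw for name in _PAIR_MACHINE.values()}
                        _, trail = route(gate, {"B": b, "T": t, "U": u}, pairwise)
                        worst = max(worst, len(trail))
    return worst


@dataclass
class CascadeModel:
    """The seven trained binary machines plus the decision routing."""

    machines: dict[str, BinaryMachine]
    hyperparameters: dict[str, tuple[float, float]] = field(default_factory=dict)
    cv_accuracy: dict[str, float] = field(default_factory=dict)
    n_features: int = 0

    def __post_init__(self) -> None:
        missing = [n for n in MACHINE_NAMES if n not in self.machines]
        if missing:
            raise ValueError(f"cascade is missing machines: {missing}")
        if len(self.machines) != 7:
            extra = set(self.machines) - set(MACHINE_NAMES)
            raise ValueError(f"cascade must have exactly 7 machines; extras: {extra}")

    def _check_length(self, f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=float).ravel()
        if len(f) != self.n_features:
            raise ValueError(
                f"feature length mismatch: expected {self.n_features}, got {len(f)}"
            )
        return f

    def predict_one(self, f: np.ndarray) -> tuple[str, list[str]]:
        """Classify one feature vector; returns (label, audit trail)."""
        f = self._check_length(f)[None, :]
        gate = float(self.machines["N|~N"].decision_values(f)[0])
        if gate > 0:
            return route(True, {})
        level2 = {
            d: float(self.machines[f"{d}|~{d}"].decision_values(f)[0])
            for d in ("B", "T", "U")
        }
        positives = [d for d in ("B", "T", "U") if level2[d] > 0]
        pairwise = None
        if len(positives) == 2:
            name = _PAIR_MACHINE[frozenset(positives)]
            pairwise = {name: float(self.machines[name].decision_values(f)[0])}
        return route(False, level2, pairwise)

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Labels for an (n, d) feature matrix."""
        x = np.atleast_2d(np.asarray(features, dtype=float))
        return np.array([self.predict_one(row)[0] for row in x])

    def decision_scores(self, features: np.ndarray) -> dict[str, np.ndarray]:
        """One-vs-rest scores per class for every row (used for ROC curves).

        N's score is the gate decision value toward normal; each disease's
        score is its level-2 machine's decision value.  All four machines
        are evaluated regardless of routing.
        """
        x = np.atleast_2d(np.asarray(features, dtype=float))
        for row in x:
            self._check_length(row)
        return {
            "N": self.machines["N|~N"].decision_values(x),
            "B": self.machines["B|~B"].decision_values(x),
            "T": self.machines["T|~T"].decision_values(x),
            "U": self.machines["U|~U"].decision_values(x),
        }


def _machine_spec(labels: np.ndarray):
    """(name, positive, negative, row-selector) for the seven machines."""
    y = np.asarray(labels)
    diseased = np.isin(y, ("B", "T", "U"))
    return [
        ("N|~N", "N", "~N", np.ones(len(y), dtype=bool), y == "N"),
        ("B|~B", "B", "~B", diseased, y == "B"),
        ("T|~T", "T", "~T", diseased, y == "T"),
        ("U|~U", "U", "~U", diseased, y == "U"),
        ("B|T", "B", "T", np.isin(y, ("B", "T")), y == "B"),
        ("B|U", "B", "U", np.isin(y, ("B", "U")), y == "B"),
        ("T|U", "T", "U", np.isin(y, ("T", "U")), y == "T"),
    ]


def train_cascade(
    features: np.ndarray,
    labels: np.ndarray,
    C_grid=DEFAULT_C_GRID,
    sigma_grid=DEFAULT_SIGMA_GRID,
    folds: int = 5,
    seed: int = 0,
) -> CascadeModel:
    """Train the seven-machine cascade with per-machine grid search.

    The gate sees all data; one-vs-rest disease machines see diseased
    images only; pairwise machines see their two classes.  Each machine's
    (C, sigma) is chosen independently by :func:`grid_search`.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    present = set(np.unique(y))
    missing_classes = [c for c in CLASSES if c not in present]
    if missing_classes:
        untrainable = [
            name
            for name, _pos, _neg, sel, is_pos in _machine_spec(y)
            if not (is_pos & sel).any() or not (~is_pos & sel).any()
        ]
        raise ValueError(
            f"classes missing from training labels: {missing_classes}; "
            f"untrainable machines: {untrainable}"
        )
    machines: dict[str, BinaryMachine] = {}
    hyper: dict[str, tuple[float, float]] = {}
    cv_acc: dict[str, float] = {}
    for idx, (name, pos, neg, sel, is_pos) in enumerate(_machine_spec(y)):
        xs = x[sel]
        ys = np.where(is_pos[sel], 1, -1)
        C, sigma, acc = grid_search(
            xs, ys, C_grid, sigma_grid, folds=folds, seed=seed + idx
        )
        machines[name] = train_binary(
            xs, ys, C, sigma, name=name, positive_label=pos, negative_label=neg
        )
        hyper[name] = (C, sigma)
        cv_acc[name] = acc
    return CascadeModel(
        machines=machines,
        hyperparameters=hyper,
        cv_accuracy=cv_acc,
        n_features=x.shape[1],
    )
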