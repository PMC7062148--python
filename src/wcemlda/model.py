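"""Model / Results interface over the hierarchical SVM cascade.

``HierarchicalSVC`` is constructed from a feature matrix and four-class
labels; ``fit()`` runs the per-machine hyperparameter search and cascade
training and returns a ``HierarchicalSVCResults`` carrying the trained
machines, the selected (C, sigma) per machine with their cross-validated
accuracies, and prediction / scoring / summary methods.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cascade import (
    DEFAULT_C_GRID,
    DEFAULT_SIGMA_GRID,
    MACHINE_NAMES,
    CascadeModel,
    train_cascade,
)


class HierarchicalSVC:
    """Four-class hierarchical SVM model specification.

    Parameters
    ----------
    features
        (n, d) feature matrix, one row per image.
    labels
        Length-n vector with values in {B, U, T, N}.
    """

    def __init__(self, features, labels):
        self.features = np.asarray(features, dtype=float)
        self.labels = np.asarray(labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if len(self.labels) != len(self.features):
            raise ValueError("features and labels lengths differ")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label"):
        """Build from a DataFrame whose non-label columns are features."""
        labels = df[label_col].to_numpy()
        features = df.drop(columns=[label_col]).to_numpy(dtype=float)
        return cls(features, labels)

    def fit(
        self,
        C_grid=DEFAULT_C_GRID,
        sigma_grid=DEFAULT_SIGMA_GRID,
        folds: int = 5,
        seed: int = 0,
    ) -> "HierarchicalSVCResults":
        cascade = train_cascade(
            self.features, self.labels, C_grid, sigma_grid, folds=folds, seed=seed
        )
        return HierarchicalSVCResults(self, cascade, seed=seed)


class HierarchicalSVCResults:
    """Fitted cascade: trained machines, hyperparameters, predictions."""

    def __init__(self, model: HierarchicalSVC, cascade: CascadeModel, seed: int = 0):
        self.model = model
        self.cascade = cascade
        self.seed = seed

    @property
    def hyperparameters(self) -> pd.DataFrame:
        """Selected (C, sigma) and grid-search CV accuracy per machine."""
        rows = []
        for name in MACHINE_NAMES:
            C, sigma = self.cascade.hyperparameters[name]
            rows.append(
                {
                    "machine": name,
                    "C": C,
                    "sigma": sigma,
                    "cv_accuracy": self.cascade.cv_accuracy[name],
                }
            )
        return pd.DataFrame(rows)

    def predict(self, features) -> np.ndarray:
        return self.cascade.predict(features)

    def predict_with_trail(self, f) -> tuple[str, list[str]]:
        """Label plus the audit trail of machines consulted for one image."""
        return self.cascade.predict_one(f)

    def decision_scores(self, features) -> dict[str, np.ndarray]:
        return self.cascade.decision_scores(features)

    def summary(self) -> str:
        counts = pd.Series(self.model.labels).value_counts()
        lines = [
            "Hierarchical SVM cascade (RBF kernel)",
            "=" * 46,
            f"Images: {len(self.model.labels)}   "
            f"Features: {self.model.features.shape[1]}",
            "Class counts: "
            + ", ".join(f"{c}={counts.get(c, 0)}" for c in ("B", "U", "T", "N")),
            "",
            self.hyperparameters.to_string(index=False, float_format="%.4g"),
        ]
        return "\n".join(lines)
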