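"""Per-image pixel-level linear discriminant models and the model bank.

Each pixel-labeled diseased image yields one two-class LDA over raw RGB
pixel intensities: diseased pixels (mask = 1) vs normal pixels (mask = 0)
inside the valid imaging field.  The trained models form an ordered bank;
applying model ``k`` to a new image marks the pixels whose color resembles
that training image's lesion, producing the candidate ROI used for feature
extraction.

The discriminant is the standard plug-in Gaussian rule with a shared
(pooled within-class) covariance and empirical class priors:

    w = Sigma^-1 (mu_1 - mu_0)
    label(x) = 1  iff  w.x > 1/2 w.(mu_1 + mu_0) - log(pi_1 / pi_0)

with ridge regularization Sigma + eps*I, eps = 1e-6 * trace(Sigma)/3, so
constant-color masks (saturated lesions) never make the solve singular.
Ties (exact equality) go to the normal class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocess import peripheral_mask
from .synthetic import LabeledImage

#: relative ridge applied to the pooled covariance diagonal
RIDGE_FRACTION = 1e-6


@dataclass
class LDAModel:
    """One trained two-class pixel discriminant."""

    mean_diseased: np.ndarray  # (3,)
    mean_normal: np.ndarray  # (3,)
    pooled_covariance: np.ndarray  # (3, 3), after regularization
    weight: np.ndarray  # (3,) = pooled_covariance^-1 (mu_d - mu_n)
    threshold: float
    prior_diseased: float
    source_image_id: str = ""
    source_class: str = ""

    def scores(self, pixels: np.ndarray) -> np.ndarray:
        """Signed discriminant value w.x - threshold for an (n, 3) array."""
        return np.asarray(pixels, dtype=float) @ self.weight - self.threshold


def train_lda(image: LabeledImage, valid: np.ndarray | None = None) -> LDAModel:
    """Train one pixel-level LDA from a pixel-labeled image.

    Parameters
    ----------
    image
        Image with a binary lesion mask; must contain at least one diseased
        and one normal pixel inside the valid field.
    valid
        Valid-field mask; computed with
        :func:`~wcemlda.preprocess.peripheral_mask` when omitted.
    """
    if image.mask is None:
        raise ValueError(f"image {image.id!r} has no pixel-level mask")
    if valid is None:
        valid = peripheral_mask(image)
    y = image.mask[valid]
    x = image.raster[valid].astype(float)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError(
            f"degenerate mask for image {image.id!r}: "
            f"{n1} diseased / {n0} normal valid pixels"
        )
    x1, x0 = x[y], x[~y]
    mu1 = x1.mean(axis=0)
    mu0 = x0.mean(axis=0)
    scatter1 = (x1 - mu1).T @ (x1 - mu1)
    scatter0 = (x0 - mu0).T @ (x0 - mu0)
    dof = max(n1 + n0 - 2, 1)
    cov = (scatter1 + scatter0) / dof
    cov = cov + RIDGE_FRACTION * (np.trace(cov) / 3.0 + 1.0) * np.eye(3)
    weight = np.linalg.solve(cov, mu1 - mu0)
    prior = n1 / (n1 + n0)
    threshold = 0.5 * weight @ (mu1 + mu0) - np.log(prior / (1.0 - prior))
    return LDAModel(
        mean_diseased=mu1,
        mean_normal=mu0,
        pooled_covariance=cov,
        weight=weight,
        threshold=float(threshold),
        prior_diseased=float(prior),
        source_image_id=image.id,
        source_class=image.label or "",
    )


@dataclass
class ROIMask:
    """Binary ROI produced by applying one bank model to an image."""

    mask: np.ndarray  # H x W bool
    model_index: int = -1


def predict_pixels(
    model: LDAModel, image: LabeledImage, valid: np.ndarray | None = None
) -> ROIMask:
    """Label every valid pixel 1 iff the diseased-class posterior wins.

    Border pixels are always 0; ties go to the normal class.
    """
    if valid is None:
        valid = peripheral_mask(image)
    h, w = image.shape
    scores = model.scores(image.raster.reshape(-1, 3)).reshape(h, w)
    return ROIMask(mask=(scores > 0) & valid)


def extract_roi(
    model: LDAModel, image: LabeledImage, valid: np.ndarray | None = None
) -> set[tuple[int, int]]:
    """Coordinate set {(i, j)} of pixels the model labels diseased."""
    ii, jj = np.nonzero(predict_pixels(model, image, valid).mask)
    return {(int(i), int(j)) for i, j in zip(ii, jj)}


@dataclass
class ModelBank:
    """Ordered collection of per-image LDA models.

    The order is fixed at build time and preserved by serialization: the
    downstream feature layout depends on it.
    """

    models: list[LDAModel] = field(default_factory=list)

    @property
    def M(self) -> int:
        return len(self.models)

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, k: int) -> LDAModel:
        return self.models[k]

    def restrict(self, source_class: str) -> "ModelBank":
        """Sub-bank of models trained on one disease class, order preserved."""
        return ModelBank([m for m in self.models if m.source_class == source_class])

    def save(self, path: str | Path) -> None:
        """Serialize to a single .npz archive (matrices + JSON metadata)."""
        arrays: dict[str, np.ndarray] = {}
        meta = {"version": 1, "M": self.M, "models": []}
        for k, m in enumerate(self.models):
            arrays[f"mean_diseased_{k}"] = m.mean_diseased
            arrays[f"mean_normal_{k}"] = m.mean_normal
            arrays[f"pooled_covariance_{k}"] = m.pooled_covariance
            arrays[f"weight_{k}"] = m.weight
            meta["models"].append(
                {
                    "threshold": m.threshold,
                    "prior_diseased": m.prior_diseased,
                    "source_image_id": m.source_image_id,
                    "source_class": m.source_class,
                }
            )
        arrays["__meta__"] = np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ModelBank":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"].tobytes()).decode("utf-8"))
            models = []
            for k, mm in enumerate(meta["models"]):
                models.append(
                    LDAModel(
                        mean_diseased=data[f"mean_diseased_{k}"],
                        mean_normal=data[f"mean_normal_{k}"],
                        pooled_covariance=data[f"pooled_covariance_{k}"],
                        weight=data[f"weight_{k}"],
                        threshold=mm["threshold"],
                        prior_diseased=mm["prior_diseased"],
                        source_image_id=mm["source_image_id"],
                        source_class=mm["source_class"],
                    )
                )
        return cls(models)


def build_bank(labeled_images: list[LabeledImage]) -> ModelBank:
    """Train one LDA per pixel-labeled image; bank order = input order."""
    if not labeled_images:
        raise ValueError("need at least one pixel-labeled image")
    models = []
    for image in labeled_images:
        try:
            models.append(train_lda(image))
        except ValueError as exc:
            raise ValueError(f"cannot train LDA for image {image.id!r}: {exc}") from exc
    return ModelBank(models)
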