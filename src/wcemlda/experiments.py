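"""Reproducible synthetic end-to-end experiments.

These drive the whole pipeline -- image generation, bank building, feature
extraction, cascade training, stratified cross-validation -- on the
well-separated synthetic regime, at sizes small enough for a single CPU:
three pixel-labeled fixtures per disease for the bank and 40 evaluation
images per class, with single small lesions (<= 2% of the imaging field)
so that ROI-based features can be contrasted with whole-image fits.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .evaluate import EvaluationReport, PipelineConfig, cross_validate
from .lda import ModelBank, build_bank
from .synthetic import DISEASE_CLASSES, LabeledImage, SyntheticConfig, generate_dataset, generate_image

#: single small lesion per image: ellipse area is at most ~1.5% of the field
SMALL_LESION_CONFIG = SyntheticConfig(
    blob_count_range=(1, 1), blob_radius_range=(6.0, 14.0)
)

#: reduced hyperparameter grids used by the benchmark experiments
BENCHMARK_PIPELINE = PipelineConfig(
    C_grid=(1.0, 32.0), sigma_grid=(1.0, 4.0, 16.0), svm_folds=3, cv_folds=10
)


def make_bank_fixtures(
    n_per_disease: int = 3,
    config: SyntheticConfig = SMALL_LESION_CONFIG,
    seed: int = 0,
) -> list[LabeledImage]:
    """Pixel-labeled diseased fixtures for bank building (B, U, T order)."""
    rng = np.random.default_rng(seed)
    images = []
    for klass in DISEASE_CLASSES:
        for i in range(n_per_disease):
            img = generate_image(klass, config, seed=int(rng.integers(0, 2**31 - 1)))
            img.id = f"bank-{klass}{i}"
            images.append(img)
    return images


def synthetic_benchmark(
    seed: int = 0,
    n_bank_per_disease: int = 3,
    n_eval_per_class: int = 40,
    config: SyntheticConfig = SMALL_LESION_CONFIG,
    pipeline: PipelineConfig = BENCHMARK_PIPELINE,
    variants: tuple[str, ...] = ("pdf",),
) -> dict[str, EvaluationReport]:
    """Cross-validated pipeline accuracy on the synthetic study conditions.

    Returns one :class:`EvaluationReport` per requested feature variant
    (``pdf``, ``whole_image``, ``count``, ``stat``), all sharing the same
    bank and evaluation images.
    """
    bank_images = make_bank_fixtures(n_bank_per_disease, config, seed=seed)
    bank = build_bank(bank_images)
    counts = {c: n_eval_per_class for c in ("B", "U", "T", "N")}
    images, _ = generate_dataset(counts, config, seed=seed + 1)
    reports = {}
    for variant in variants:
        reports[variant] = cross_validate(
            images, bank, replace(pipeline, feature_variant=variant), seed=seed
        )
    return reports


def bank_and_eval_images(
    seed: int = 0,
    n_bank_per_disease: int = 3,
    n_eval_per_class: int = 40,
    config: SyntheticConfig = SMALL_LESION_CONFIG,
) -> tuple[ModelBank, list[LabeledImage]]:
    """Convenience: the benchmark's fixed bank and evaluation images."""
    bank = build_bank(make_bank_fixtures(n_bank_per_disease, config, seed=seed))
    counts = {c: n_eval_per_class for c in ("B", "U", "T", "N")}
    images, _ = generate_dataset(counts, config, seed=seed + 1)
    return bank, images
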