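"""PDF-parameter feature extraction from LDA-bank ROIs.

For each model in the bank, the ROI is predicted on the RGB raster (the
discriminants are trained in RGB); the image is converted to the chosen
color space and the ROI intensities of every channel are summarised by the
maximum-likelihood parameters of a chosen density family.  Concatenating
the fitted parameters over models and channels -- in bank order, then
channel order, then parameter order -- yields the image's feature vector:

    f_k = [ params(channel 1 | ROI_k), params(channel 2 | ROI_k), ... ]
    F   = [ f_1  f_2  ...  f_M ]

A normal fit contributes (mu, sigma) per channel (so a 10-model bank in a
3-channel space gives 10 x 3 x 2 = 60 features); Rayleigh and exponential
contribute one scale parameter each.  A model that fires on no pixel
contributes an all-zero block, distinguishable from any real fit.

Variant extractors (pixel counts, order statistics, whole-image fits) are
provided for ablation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor

from .lda import ModelBank, predict_pixels
from .preprocess import peripheral_mask
from .synthetic import LabeledImage

FAMILIES = ("normal", "rayleigh", "exponential")
COLOR_SPACES = ("RGB", "YIQ", "LAB", "HSV", "YCbCr", "CMYK")

_CHANNEL_NAMES = {
    "RGB": ("R", "G", "B"),
    "YIQ": ("Y", "I", "Q"),
    "LAB": ("L", "a", "b"),
    "HSV": ("H", "S", "V"),
    "YCbCr": ("Y", "Cb", "Cr"),
    "CMYK": ("C", "M", "Y", "K"),
}

STAT_NAMES = ("mean", "median", "mode", "sd")


def convert_colorspace(
    image: LabeledImage, space: str = "RGB"
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Convert the raster to a color space, on each channel's native scale.

    RGB stays on [0, 255]; HSV is the hexcone transform on unit scales;
    LAB is CIE L*a*b* under D65 sRGB (L in [0, 100]); YIQ and YCbCr follow
    ITU-R BT.601 (YCbCr on the 16-235 / 16-240 digital range); CMYK is the
    naive complement transform on unit scales (4 channels).
    """
    if space not in COLOR_SPACES:
        raise ValueError(f"unknown color space {space!r}; expected one of {COLOR_SPACES}")
    rgb01 = image.raster.astype(float) / 255.0
    if space == "RGB":
        out = image.raster.astype(float)
    elif space == "HSV":
        out = skcolor.rgb2hsv(rgb01)
    elif space == "LAB":
        out = skcolor.rgb2lab(rgb01)
    elif space == "YIQ":
        out = skcolor.rgb2yiq(rgb01)
    elif space == "YCbCr":
        out = skcolor.rgb2ycbcr(rgb01)
    else:  # CMYK
        k = 1.0 - rgb01.max(axis=2)
        denom = np.where(k < 1.0, 1.0 - k, 1.0)
        c = (1.0 - rgb01[..., 0] - k) / denom
        m = (1.0 - rgb01[..., 1] - k) / denom
        y = (1.0 - rgb01[..., 2] - k) / denom
        out = np.stack([c, m, y, k], axis=2)
    return out, _CHANNEL_NAMES[space]


@dataclass(frozen=True)
class PDFParams:
    """Maximum-likelihood parameters of one channel fit."""

    family: str
    params: tuple[float, ...]  # normal: (mu, sigma); rayleigh/exponential: (scale,)


def params_per_fit(family: str) -> int:
    if family not in FAMILIES:
        raise ValueError(f"unknown PDF family {family!r}; expected one of {FAMILIES}")
    return 2 if family == "normal" else 1


def fit_pdf(values: np.ndarray, family: str) -> PDFParams:
    """Closed-form MLE fit of one density family to channel samples.

    normal: mu = mean, sigma = sqrt(sum((x-mu)^2)/n)  (n-denominator)
    rayleigh: sigma = sqrt(sum(x^2) / (2n))
    exponential: scale = mean
    Empty samples return the all-zero sentinel block.

    Rayleigh and exponential densities have nonnegative support, so they
    are fitted to intensity magnitudes |x|; this is a no-op on ordinary
    intensity channels and keeps the scale estimate well defined on signed
    opponent channels (YIQ I/Q, LAB a*/b*).
    """
    p = params_per_fit(family)
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        return PDFParams(family, (0.0,) * p)
    if family == "normal":
        mu = float(x.mean())
        sigma = float(np.sqrt(np.mean((x - mu) ** 2)))
        return PDFParams(family, (mu, sigma))
    if family == "rayleigh":
        return PDFParams(family, (float(np.sqrt(np.mean(x**2) / 2.0)),))
    return PDFParams(family, (float(np.abs(x).mean()),))


@dataclass
class FeatureVector:
    """Flat feature vector plus its (model, channel, name) layout."""

    values: np.ndarray
    layout: list[tuple[int, str, str]]  # (model_index, channel, param/stat name)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.layout):
            raise ValueError("feature values and layout lengths differ")

    def __len__(self) -> int:
        return len(self.values)


_PARAM_NAMES = {"normal": ("mu", "sigma"), "rayleigh": ("sigma",), "exponential": ("scale",)}


def _roi_masks(image: LabeledImage, bank: ModelBank, valid: np.ndarray) -> list[np.ndarray]:
    return [predict_pixels(m, image, valid).mask for m in bank]


def extract_features(
    image: LabeledImage,
    bank: ModelBank,
    family: str = "normal",
    space: str = "RGB",
    valid: np.ndarray | None = None,
) -> FeatureVector:
    """PDF-parameter feature vector of one image under a model bank.

    Length = M x C x p for M bank models, C channels and p parameters per
    fit.  ROIs are always predicted on the RGB raster; only the fitted
    intensities use the converted space.
    """
    if bank.M < 1:
        raise ValueError("model bank is empty")
    p_names = _PARAM_NAMES[_validate_family(family)]
    if valid is None:
        valid = peripheral_mask(image)
    converted, channels = convert_colorspace(image, space)
    values: list[float] = []
    layout: list[tuple[int, str, str]] = []
    for k, roi in enumerate(_roi_masks(image, bank, valid)):
        for c, channel in enumerate(channels):
            fit = fit_pdf(converted[..., c][roi], family)
            for name, v in zip(p_names, fit.params):
                values.append(v)
                layout.append((k, channel, name))
    return FeatureVector(np.array(values), layout)


def _validate_family(family: str) -> str:
    if family not in FAMILIES:
        raise ValueError(f"unknown PDF family {family!r}; expected one of {FAMILIES}")
    return family


def count_features(
    image: LabeledImage, bank: ModelBank, valid: np.ndarray | None = None
) -> FeatureVector:
    """ROI pixel counts |S_k| per bank model (ablation variant); length M."""
    if valid is None:
        valid = peripheral_mask(image)
    values = [float(roi.sum()) for roi in _roi_masks(image, bank, valid)]
    layout = [(k, "*", "count") for k in range(bank.M)]
    return FeatureVector(np.array(values), layout)


def stat_features(
    image: LabeledImage,
    bank: ModelBank,
    space: str = "RGB",
    valid: np.ndarray | None = None,
) -> FeatureVector:
    """Order statistics (mean, median, mode, sd) per model per channel.

    The mode is the most frequent value, smallest value on ties; sd uses
    the population (n) denominator.  Empty ROIs yield zeros.
    """
    if valid is None:
        valid = peripheral_mask(image)
    converted, channels = convert_colorspace(image, space)
    values: list[float] = []
    layout: list[tuple[int, str, str]] = []
    for k, roi in enumerate(_roi_masks(image, bank, valid)):
        for c, channel in enumerate(channels):
            x = converted[..., c][roi]
            if x.size == 0:
                stats = (0.0, 0.0, 0.0, 0.0)
            else:
                uniq, counts = np.unique(x, return_counts=True)
                mode = uniq[np.argmax(counts)]  # np.unique sorts -> ties -> smallest
                stats = (
                    float(x.mean()),
                    float(np.median(x)),
                    float(mode),
                    float(x.std()),
                )
            for name, v in zip(STAT_NAMES, stats):
                values.append(v)
                layout.append((k, channel, name))
    return FeatureVector(np.array(values), layout)


def whole_image_features(
    image: LabeledImage,
    family: str = "normal",
    space: str = "RGB",
    valid: np.ndarray | None = None,
) -> FeatureVector:
    """One PDF fit per channel over all valid-field pixels (no ROI).

    Equivalent to :func:`extract_features` with a single hypothetical model
    whose ROI is the entire valid field; length C x p.
    """
    p_names = _PARAM_NAMES[_validate_family(family)]
    if valid is None:
        valid = peripheral_mask(image)
    converted, channels = convert_colorspace(image, space)
    values: list[float] = []
    layout: list[tuple[int, str, str]] = []
    for c, channel in enumerate(channels):
        fit = fit_pdf(converted[..., c][valid], family)
        for name, v in zip(p_names, fit.params):
            values.append(v)
            layout.append((0, channel, name))
    return FeatureVector(np.array(values), layout)


def featurize_dataset(
    images: list[LabeledImage],
    bank: ModelBank,
    variant: str = "pdf",
    family: str = "normal",
    space: str = "RGB",
):
    """Feature matrix (one row per image) for a dataset.

    Returns ``(X, labels, ids, layout)`` with X of shape (n_images, d).
    ``variant`` is one of ``pdf``, ``count``, ``stat``, ``whole_image``.
    """
    rows, layout = [], None
    for image in images:
        valid = peripheral_mask(image)
        if variant == "pdf":
            fv = extract_features(image, bank, family, space, valid)
        elif variant == "count":
            fv = count_features(image, bank, valid)
        elif variant == "stat":
            fv = stat_features(image, bank, space, valid)
        elif variant == "whole_image":
            fv = whole_image_features(image, family, space, valid)
        else:
            raise ValueError(
                f"unknown feature variant {variant!r}; "
                "expected pdf, count, stat or whole_image"
            )
        rows.append(fv.values)
        layout = fv.layout
    x = np.vstack(rows) if rows else np.empty((0, 0))
    labels = np.array([img.label for img in images])
    ids = [img.id for img in images]
    return x, labels, ids, layout
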