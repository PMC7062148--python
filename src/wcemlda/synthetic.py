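"""Synthetic wireless-capsule-endoscopy (WCE) image generator.

Real WCE frames show a bright circular imaging field surrounded by a black
peripheral border, a mucosa-colored background, and -- in diseased frames --
lesions whose pixel colors are characteristic of the disease: saturated dark
red for bleeding, pale yellow-white for ulcer, pink for tumor.  This module
emulates exactly those features so that the pixel-level discriminant bank,
the PDF-feature extractor and the cascade classifier can be trained and
evaluated end-to-end without access to clinical data.

Each generated image carries a pixel-exact ground-truth lesion mask and an
image-level class label in {B, U, T, N} (bleeding, ulcer, tumor, normal).
Generation is fully deterministic given a config and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage as ndi

CLASSES = ("B", "U", "T", "N")
DISEASE_CLASSES = ("B", "U", "T")


@dataclass(frozen=True)
class ColorModel:
    """Multivariate normal RGB color model for one pixel population."""

    mean: tuple[float, float, float]
    cov: tuple[tuple[float, ...], ...] = (
        (64.0, 0.0, 0.0),
        (0.0, 64.0, 0.0),
        (0.0, 0.0, 64.0),
    )

    def validate(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        if mean.shape != (3,) or np.any(mean < 0) or np.any(mean > 255):
            raise ValueError(f"color mean must be 3 values in [0, 255], got {self.mean}")
        if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
            raise ValueError("covariance must be a symmetric 3x3 matrix")
        eigvals = np.linalg.eigvalsh(cov)
        if np.any(eigvals < -1e-9):
            raise ValueError("covariance must be positive semi-definite")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` RGB triples (float, unclipped)."""
        cov = np.asarray(self.cov, dtype=float)
        # stabilised Cholesky so diagonal-zero (constant-color) models work
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(3))
        z = rng.standard_normal((n, 3))
        return np.asarray(self.mean, dtype=float) + z @ chol.T


# Default fixture palette: qualitatively matches endoscopic appearance
# (red blood, whitish ulcer, pinkish tumor on reddish-brown mucosa) while
# keeping the classes linearly separable in RGB.
DEFAULT_LESION_COLORS: dict[str, ColorModel] = {
    "B": ColorModel(mean=(185.0, 35.0, 35.0)),
    "U": ColorModel(mean=(215.0, 205.0, 165.0)),
    "T": ColorModel(mean=(200.0, 120.0, 140.0)),
}
DEFAULT_BACKGROUND_COLOR = ColorModel(mean=(160.0, 95.0, 70.0))


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic WCE image distribution.

    Attributes
    ----------
    image_size
        (height, width) in pixels.
    border_radius_fraction
        Radius of the circular imaging field as a fraction of
        ``min(H, W) / 2``; pixels outside are black border.
    lesion_colors
        Per-disease RGB color model for lesion pixels.
    background_color
        RGB color model for mucosa background pixels.
    blob_count_range
        Inclusive (min, max) number of lesion blobs in a diseased image.
    blob_radius_range
        Inclusive (min, max) ellipse semi-axis length, pixels.
    pixel_noise_sd
        Optional additive white sensor noise, 8-bit intensity units.
    illumination_sd
        Standard deviation of the per-image global color shift (8-bit
        units): one RGB offset is drawn per image and added to every field
        pixel, emulating the frame-to-frame illumination and mucosa-tone
        variability of real capsule video.  Whole-image color statistics
        are confounded by this shift; lesion-vs-mucosa contrast within an
        image is not.
    gradient_sd
        Standard deviation of the per-channel amplitude of a smooth planar
        illumination ramp across the field (8-bit units), emulating
        directional lighting and vignetting.  The ramp direction is random
        per image; amplitudes are drawn per channel.  This makes global
        intensity variance a nuisance quantity, as in real frames, while
        leaving local lesion-vs-mucosa contrast intact.
    feather_sigma
        Gaussian feathering of blob edges in the rendered raster (pixels);
        the ground-truth mask stays the sharp ellipse.
    """

    image_size: tuple[int, int] = (256, 256)
    border_radius_fraction: float = 0.9
    lesion_colors: dict[str, ColorModel] = field(
        default_factory=lambda: dict(DEFAULT_LESION_COLORS)
    )
    background_color: ColorModel = DEFAULT_BACKGROUND_COLOR
    blob_count_range: tuple[int, int] = (1, 3)
    blob_radius_range: tuple[float, float] = (6.0, 20.0)
    pixel_noise_sd: float = 0.0
    illumination_sd: float = 10.0
    gradient_sd: float = 25.0
    feather_sigma: float = 1.0

    def validate(self) -> None:
        h, w = self.image_size
        if h < 8 or w < 8:
            raise ValueError("image_size must be at least 8x8")
        if not 0.0 < self.border_radius_fraction <= 1.0:
            raise ValueError("border_radius_fraction must be in (0, 1]")
        lo, hi = self.blob_count_range
        if lo < 1 or hi < lo:
            raise ValueError("blob_count_range must satisfy 1 <= min <= max")
        rlo, rhi = self.blob_radius_range
        if rlo <= 0 or rhi < rlo:
            raise ValueError("blob_radius_range must satisfy 0 < min <= max")
        if self.pixel_noise_sd < 0:
            raise ValueError("pixel_noise_sd must be >= 0")
        if self.illumination_sd < 0:
            raise ValueError("illumination_sd must be >= 0")
        if self.gradient_sd < 0:
            raise ValueError("gradient_sd must be >= 0")
        self.background_color.validate()
        for klass in DISEASE_CLASSES:
            if klass not in self.lesion_colors:
                raise ValueError(f"lesion_colors missing class {klass!r}")
            self.lesion_colors[klass].validate()

    def field_mask(self) -> np.ndarray:
        """Boolean mask of the circular imaging field (True = inside)."""
        h, w = self.image_size
        radius = self.border_radius_fraction * min(h, w) / 2.0
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


@dataclass
class LabeledImage:
    """An 8-bit RGB raster with optional lesion mask and class label."""

    raster: np.ndarray  # H x W x 3 uint8
    mask: np.ndarray | None = None  # H x W bool, True = diseased pixel
    label: str | None = None  # one of B, U, T, N
    id: str = ""

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster)
        if self.raster.ndim != 3 or self.raster.shape[2] != 3:
            raise ValueError("raster must be H x W x 3")
        if self.raster.dtype != np.uint8:
            raise ValueError("raster must be 8-bit (uint8)")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.raster.shape[:2]:
                raise ValueError("mask shape must match raster H x W")
        if self.label is not None and self.label not in CLASSES:
            raise ValueError(f"unknown class label {self.label!r}")
        if self.label == "N" and self.mask is not None and self.mask.any():
            raise ValueError("normal-class image cannot have diseased pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape[:2]


def _sample_blobs(
    config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Union of axis-aligned elliptical blob masks, kept inside the field."""
    h, w = config.image_size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    field_radius = config.border_radius_fraction * min(h, w) / 2.0
    lo, hi = config.blob_count_range
    n_blobs = int(rng.integers(lo, hi + 1))
    rlo, rhi = config.blob_radius_range
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(n_blobs):
        a = rng.uniform(rlo, rhi)  # semi-axis along x
        b = rng.uniform(rlo, rhi)  # semi-axis along y
        # place the whole ellipse strictly inside the field with a 2 px margin
        max_off = max(field_radius - max(a, b) - 2.0, 0.0)
        r = max_off * np.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * np.pi)
        bcy = cy + r * np.sin(theta)
        bcx = cx + r * np.cos(theta)
        mask |= ((yy - bcy) / b) ** 2 + ((xx - bcx) / a) ** 2 <= 1.0
    return mask


def generate_image(
    klass: str, config: SyntheticConfig | None = None, seed: int = 0
) -> LabeledImage:
    """Generate one synthetic WCE image of the given class.

    Parameters
    ----------
    klass
        Image class: ``"B"`` (bleeding), ``"U"`` (ulcer), ``"T"`` (tumor)
        or ``"N"`` (normal, no lesion).
    config
        Generator configuration; defaults to :class:`SyntheticConfig`.
    seed
        Seed for the per-image random stream; identical (config, seed)
        pairs produce bit-identical images.
    """
    if klass not in CLASSES:
        raise ValueError(f"unknown class label {klass!r}; expected one of {CLASSES}")
    config = config if config is not None else SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    h, w = config.image_size
    field = config.field_mask()
    illumination = rng.normal(0.0, config.illumination_sd, 3) if config.illumination_sd else np.zeros(3)
    if config.gradient_sd > 0:
        theta = rng.uniform(0.0, 2.0 * np.pi)
        amplitudes = rng.normal(0.0, config.gradient_sd, 3)
        yy, xx = np.mgrid[0:h, 0:w]
        # planar ramp spanning [-0.5, 0.5] across the shorter image axis
        ramp = (
            np.cos(theta) * (xx - (w - 1) / 2.0) + np.sin(theta) * (yy - (h - 1) / 2.0)
        ) / min(h, w)
        gradient = ramp[..., None] * amplitudes
    else:
        gradient = np.zeros((h, w, 3))

    raster = np.zeros((h, w, 3), dtype=float)
    raster[field] = config.background_color.sample(rng, int(field.sum()))

    if klass == "N":
        mask = np.zeros((h, w), dtype=bool)
    else:
        mask = _sample_blobs(config, rng) & field
        if config.feather_sigma > 0:
            alpha = np.clip(
                ndi.gaussian_filter(mask.astype(float), config.feather_sigma), 0.0, 1.0
            )
        else:
            alpha = mask.astype(float)
        # blend lesion color over the feather support; truth mask stays sharp
        support = (alpha > 0) & field
        lesion = config.lesion_colors[klass].sample(rng, int(support.sum()))
        a = alpha[support, None]
        raster[support] = a * lesion + (1 - a) * raster[support]

    raster[field] += illumination + gradient[field]
    if config.pixel_noise_sd > 0:
        raster[field] += rng.normal(0.0, config.pixel_noise_sd, (int(field.sum()), 3))

    raster[~field] = 0.0
    raster = np.clip(np.rint(raster), 0, 255).astype(np.uint8)
    return LabeledImage(
        raster=raster,
        mask=mask,
        label=klass,
        id=f"{klass}-{seed}",
    )


def generate_dataset(
    n_per_class: dict[str, int],
    config: SyntheticConfig | None = None,
    seed: int = 0,
) -> tuple[list[LabeledImage], pd.DataFrame]:
    """Generate a labeled dataset plus its manifest.

    Returns the images (grouped by class in B, U, T, N order) and a manifest
    DataFrame with columns ``id, label, image_path, mask_path`` (paths are
    filled by :func:`save_dataset`).  Deterministic under ``seed``.
    """
    config = config if config is not None else SyntheticConfig()
    for klass, count in n_per_class.items():
        if klass not in CLASSES:
            raise ValueError(f"unknown class label {klass!r}")
        if count < 0:
            raise ValueError(f"negative count for class {klass!r}: {count}")
    rng = np.random.default_rng(seed)
    images: list[LabeledImage] = []
    rows = []
    for klass in CLASSES:
        for i in range(n_per_class.get(klass, 0)):
            img_seed = int(rng.integers(0, 2**31 - 1))
            img = generate_image(klass, config, seed=img_seed)
            img.id = f"{klass}{i:03d}"
            images.append(img)
            rows.append({"id": img.id, "label": klass, "image_path": "", "mask_path": ""})
    manifest = pd.DataFrame(rows, columns=["id", "label", "image_path", "mask_path"])
    return images, manifest


def save_dataset(
    images: list[LabeledImage], manifest: pd.DataFrame, outdir: str | Path
) -> pd.DataFrame:
    """Write images (PNG), masks (0/255 single-channel PNG) and manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    for img in images:
        image_path = outdir / f"{img.id}.png"
        iio.imwrite(image_path, img.raster)
        row = manifest["id"] == img.id
        manifest.loc[row, "image_path"] = image_path.name
        if img.mask is not None:
            mask_path = outdir / f"{img.id}_mask.png"
            iio.imwrite(mask_path, (img.mask.astype(np.uint8) * 255))
            manifest.loc[row, "mask_path"] = mask_path.name
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def load_dataset(manifest_path: str | Path) -> list[LabeledImage]:
    """Load a dataset from a manifest CSV written by :func:`save_dataset`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    images = []
    for _, row in manifest.iterrows():
        raster = iio.imread(root / row["image_path"])[..., :3]
        mask = None
        if row.get("mask_path", ""):
            mask = iio.imread(root / row["mask_path"]) > 0
        label = row["label"] if row.get("label", "") in CLASSES else None
        images.append(
            LabeledImage(raster=raster, mask=mask, label=label, id=str(row["id"]))
        )
    return images


def separable_config(**overrides) -> SyntheticConfig:
    """The well-separated fixture regime: class color means >= 60 intensity
    units apart on at least one channel with sd 8 and no illumination
    nuisance, so a pixel-level Bayes classifier on the generating
    distributions is near-perfect -- across images, not just within one."""
    base = replace(SyntheticConfig(), illumination_sd=0.0, gradient_sd=0.0)
    return replace(base, **overrides)
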