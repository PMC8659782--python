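"""Image preprocessing: resize, Gaussian denoise, grayscale, Otsu, morphology.

The chain turns a raw RGB capture of a single root on a bright background into
the grayscale image and cleaned binary mask consumed by all feature
extractors: resize to a working resolution, Gaussian filter, luma grayscale,
Otsu threshold, opening + closing + hole filling, and retention of the largest
connected component.

Conventions: arrays are row-major with origin at the top-left, 0-based.
Grayscale uses the ITU-R 601 luma weights (0.299, 0.587, 0.114).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.transform import resize as _sk_resize

from .exceptions import (
    DegenerateHistogramError,
    InputError,
    ParameterError,
    SegmentationError,
)

__all__ = [
    "PreprocessConfig",
    "PreprocessResult",
    "resize_image",
    "gaussian_denoise",
    "to_grayscale",
    "otsu_threshold",
    "morphological_clean",
    "preprocess",
]

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the preprocessing chain.

    ``resize_to=None`` keeps the native resolution (typical 1280x1024 camera
    captures are downsampled to 512x512; synthetic fixtures are already small).
    ``gaussian_sigma=None`` derives sigma from the kernel size with the usual
    0.3*((k-1)/2 - 1) + 0.8 rule.
    """

    resize_to: tuple[int, int] | None = (512, 512)
    gaussian_kernel: int = 5
    gaussian_sigma: float | None = None
    morph_kernel: int = 5
    #: when set, the intermediate grayscale and mask are written here as PNGs
    debug_dir: str | None = None


@dataclass(frozen=True)
class PreprocessResult:
    rgb: np.ndarray
    gray: np.ndarray
    mask: np.ndarray
    threshold: int


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.size == 0:
        raise InputError("empty image")
    if img.ndim != 3 or img.shape[2] != 3:
        raise InputError(f"expected H x W x 3 RGB array, got shape {img.shape}")
    if img.shape[0] < 32 or img.shape[1] < 32:
        raise InputError("image must be at least 32 x 32")
    return img


def resize_image(img: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Bilinear resize to ``target = (height, width)``."""
    img = _check_rgb(img)
    th, tw = target
    if th < 32 or tw < 32:
        raise ParameterError("target dimensions must be >= 32")
    if (th, tw) == img.shape[:2]:
        return img.copy()
    out = _sk_resize(
        img.astype(float), (th, tw, 3), order=1, mode="reflect",
        anti_aliasing=False, preserve_range=True,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def gaussian_kernel_2d(size: int, sigma: float) -> np.ndarray:
    """Normalized 2-D Gaussian kernel truncated to ``size x size``."""
    ax = np.arange(size) - (size - 1) / 2.0
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    return k / k.sum()


def default_sigma(kernel: int) -> float:
    return 0.3 * ((kernel - 1) * 0.5 - 1) + 0.8


def gaussian_denoise(
    img: np.ndarray, kernel: int = 5, sigma: float | None = None
) -> np.ndarray:
    """Per-channel convolution with a normalized Gaussian; reflected borders."""
    img = _check_rgb(img)
    if kernel < 1 or kernel % 2 == 0:
        raise ParameterError(f"kernel must be odd and >= 1, got {kernel}")
    if kernel == 1:
        return img.copy()
    if sigma is None:
        sigma = default_sigma(kernel)
    k2 = gaussian_kernel_2d(kernel, sigma)
    out = np.empty_like(img, dtype=float)
    for ch in range(3):
        out[..., ch] = ndi.convolve(img[..., ch].astype(float), k2, mode="reflect")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """ITU-R 601 luma grayscale of an 8-bit RGB image."""
    img = _check_rgb(img)
    return np.clip(np.rint(img.astype(float) @ _LUMA), 0, 255).astype(np.uint8)


def otsu_threshold(gray: np.ndarray) -> int:
    """Otsu's threshold: the split maximizing between-class variance.

    Returns the smallest t in [0, 254] maximizing the between-class variance
    of the {<= t, > t} split of the intensity histogram.
    """
    gray = np.asarray(gray)
    hist = np.bincount(gray.ravel().astype(np.uint8), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("image has fewer than 2 distinct values")
    total = hist.sum()
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(hist)[:-1]  # pixels <= t, t = 0..254
    w1 = total - w0
    csum = np.cumsum(hist * levels)[:-1]
    mu_total = (hist * levels).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = csum / w0
        mu1 = (mu_total - csum) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between[np.isnan(var_between)] = -np.inf
    return int(np.argmax(var_between))  # argmax returns the smallest tie


def morphological_clean(mask: np.ndarray, kernel: int = 5) -> np.ndarray:
    """Opening then closing with a square element, then fill enclosed holes."""
    if kernel < 3 or kernel % 2 == 0:
        raise ParameterError(f"kernel must be odd and >= 3, got {kernel}")
    mask = np.asarray(mask).astype(bool)
    structure = np.ones((kernel, kernel), dtype=bool)
    out = ndi.binary_opening(mask, structure=structure)
    out = ndi.binary_closing(out, structure=structure)
    return ndi.binary_fill_holes(out)


def preprocess(
    img: np.ndarray, config: PreprocessConfig | None = None
) -> PreprocessResult:
    """Full chain: resize, filter, grayscale, Otsu, clean, keep largest blob.

    The specimen side of the threshold is taken as the side with the smaller
    total intensity (mean intensity x area), which selects the dark root
    against the bright background regardless of polarity.
    """
    cfg = config or PreprocessConfig()
    img = _check_rgb(img)
    if cfg.resize_to is not None:
        img = resize_image(img, cfg.resize_to)
    img = gaussian_denoise(img, cfg.gaussian_kernel, cfg.gaussian_sigma)
    gray = to_grayscale(img)
    try:
        t = otsu_threshold(gray)
    except DegenerateHistogramError as exc:
        raise SegmentationError(f"cannot segment: {exc}") from exc
    low = gray <= t
    g = gray.astype(float)
    fg = low if g[low].sum() <= g[~low].sum() else ~low
    mask = morphological_clean(fg, cfg.morph_kernel)
    labels, n = ndi.label(mask)
    if n == 0:
        raise SegmentationError("empty foreground after morphological cleaning")
    sizes = np.bincount(labels.ravel())[1:]
    mask = labels == (int(np.argmax(sizes)) + 1)
    if cfg.debug_dir is not None:
        from pathlib import Path

        from PIL import Image

        out = Path(cfg.debug_dir)
        out.mkdir(parents=True, exist_ok=True)
        Image.fromarray(gray).save(out / "gray.png")
        Image.fromarray((mask * np.uint8(255))).save(out / "mask.png")
    return PreprocessResult(rgb=img, gray=gray, mask=mask, threshold=t)
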