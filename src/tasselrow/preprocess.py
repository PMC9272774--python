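"""Segmentation front end: raw RGB frame → cleaned binary tassel mask.

At the tasseling stage the row feature is the tassel, not the leaf canopy,
and the usual excess-green index fails because the colour components of
tassels, leaves and soil are tightly bunched.  The front end therefore

1. keeps only the lower portion of the frame (the navigation area) and
   resizes it to a square working frame,
2. stretches the dark end of each RGB channel with a logarithmic map
   ``Out = C · log(1 + p)``,
3. masks pixels whose HSV coordinates (half-degree hue convention,
   H ∈ [0, 179], S, V ∈ [0, 255]) fall inside fixed tassel thresholds,
4. grayscales and binarises the masked image with Otsu's method, and
5. cleans the binary mask with one 3×3 dilation and a 9×9 median filter.

All steps are deterministic, pure functions of (image, params).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.color import rgb2hsv

from .config import PreprocessParams
from .errors import ConfigError, InvalidInputError

__all__ = [
    "crop_and_resize",
    "log_transform",
    "log_lut",
    "rgb_to_hsv_int",
    "hsv_mask",
    "to_gray",
    "otsu_binarize",
    "OtsuResult",
    "morph_clean",
    "preprocess_frame",
    "PreprocessResult",
]

_LUMA = np.array([0.299, 0.587, 0.114])


def _as_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidInputError(f"expected H×W×3 RGB image, got shape {img.shape}")
    if img.shape[0] == 0 or img.shape[1] == 0:
        raise InvalidInputError("degenerate image with zero area")
    return img


def crop_and_resize(img: np.ndarray, params: PreprocessParams | None = None) -> np.ndarray:
    """Keep the bottom ``crop_fraction`` of the rows and resize to a square.

    The aspect ratio is deliberately not preserved: the whole pipeline is
    calibrated on a fixed square working frame (default 600×600).
    """
    params = params or PreprocessParams()
    img = _as_rgb(img)
    h = img.shape[0]
    keep = max(1, round(h * params.crop_fraction))
    cropped = img[h - keep :, :, :]
    size = params.target_size
    if cropped.shape[0] == size and cropped.shape[1] == size:
        return cropped.astype(np.uint8, copy=True)
    resized = Image.fromarray(cropped.astype(np.uint8)).resize(
        (size, size), resample=Image.BILINEAR
    )
    return np.asarray(resized, dtype=np.uint8)


def log_lut(params: PreprocessParams | None = None) -> np.ndarray:
    """256-entry lookup table of the log map ``clip(round(C·log(1+p)), 0, 255)``."""
    params = params or PreprocessParams()
    p = np.arange(256, dtype=np.float64)
    logf = np.log if params.log_base == "natural" else np.log10
    out = params.C * logf(1.0 + p)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def log_transform(img: np.ndarray, params: PreprocessParams | None = None) -> np.ndarray:
    """Apply the per-channel logarithmic contrast stretch ``Out = C·log(1+p)``.

    Values that exceed 255 (with the default natural log and C = 48 this
    happens for p ≳ 203) are clipped, not rescaled, so that the fixed HSV
    thresholds downstream keep their meaning.  The map is monotone
    non-decreasing in p.
    """
    img = _as_rgb(img)
    return log_lut(params)[img.astype(np.uint8)]


def rgb_to_hsv_int(img: np.ndarray) -> np.ndarray:
    """RGB (uint8) → HSV on the integer convention H∈[0,179], S,V∈[0,255].

    Hue is halved degrees (the convention the fixed thresholds are stated
    in); values are rounded to the nearest integer.
    """
    img = _as_rgb(img)
    hsv = rgb2hsv(img.astype(np.uint8))
    out = np.empty_like(img, dtype=np.int64)
    out[..., 0] = np.rint(hsv[..., 0] * 180.0) % 180
    out[..., 1] = np.rint(hsv[..., 1] * 255.0)
    out[..., 2] = np.rint(hsv[..., 2] * 255.0)
    return out


def hsv_mask(img: np.ndarray, params: PreprocessParams | None = None) -> np.ndarray:
    """Zero every pixel whose HSV coordinates leave the tassel gamut.

    Range endpoints are inclusive on all three channels.  Returns the masked
    RGB image (retained pixels keep their original value), which is then
    grayscaled and Otsu-binarised.
    """
    params = params or PreprocessParams()
    img = _as_rgb(img)
    hsv = rgb_to_hsv_int(img)
    keep = np.ones(img.shape[:2], dtype=bool)
    for ch, (lo, hi) in enumerate((params.h_range, params.s_range, params.v_range)):
        if lo > hi:
            raise ConfigError(f"empty HSV range on channel {ch}: [{lo}, {hi}]")
        keep &= (hsv[..., ch] >= lo) & (hsv[..., ch] <= hi)
    out = np.zeros_like(img, dtype=np.uint8)
    out[keep] = img[keep]
    return out


def to_gray(img: np.ndarray) -> np.ndarray:
    """Luma grayscale (0.299 R + 0.587 G + 0.114 B), rounded to uint8."""
    img = _as_rgb(img)
    return np.clip(np.rint(img.astype(np.float64) @ _LUMA), 0, 255).astype(np.uint8)


class OtsuResult(NamedTuple):
    threshold: int
    mask: np.ndarray
    degenerate: bool


def otsu_binarize(gray: np.ndarray) -> OtsuResult:
    """Binarise by maximising between-class variance over the 256-bin histogram.

    Pixels strictly greater than the returned threshold become 255.  Ties
    between maximising thresholds are broken toward the smallest.  A constant
    image has a single class: the result is flagged degenerate with an empty
    foreground and the constant value as threshold.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise InvalidInputError(f"expected single-channel image, got shape {gray.shape}")
    hist = np.bincount(gray.astype(np.uint8).ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    nonzero = np.flatnonzero(hist)
    if nonzero.size <= 1:
        value = int(nonzero[0]) if nonzero.size else 0
        return OtsuResult(value, np.zeros_like(gray, dtype=np.uint8), True)

    # cumulative class weight and mean; threshold t puts [0, t] in class 0
    w0 = np.cumsum(hist)
    mu = np.cumsum(hist * np.arange(256))
    mu_t = mu[-1]
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_t * w0 - mu * total) ** 2 / (w0 * w1)
    between = np.where((w0 > 0) & (w1 > 0), between, -np.inf)
    t = int(np.argmax(between[:255]))  # t = 255 leaves class 1 empty
    mask = np.where(gray > t, 255, 0).astype(np.uint8)
    return OtsuResult(t, mask, False)


def morph_clean(mask: np.ndarray, params: PreprocessParams | None = None) -> np.ndarray:
    """One square dilation followed by a median filter; output stays binary.

    The dilation inflates the thin tassel skeletons so they survive the
    median, which in turn removes isolated impulse noise.
    """
    params = params or PreprocessParams()
    mask = np.asarray(mask)
    binary = mask > 0
    if params.dilation_iters > 0:
        footprint = np.ones((params.dilation_kernel, params.dilation_kernel), dtype=bool)
        binary = ndimage.binary_dilation(binary, structure=footprint, iterations=params.dilation_iters)
    out = ndimage.median_filter(
        binary.astype(np.uint8), size=params.median_kernel, mode="constant", cval=0
    )
    return (out * 255).astype(np.uint8)


class PreprocessResult(NamedTuple):
    mask: np.ndarray          # uint8 {0, 255}, target_size × target_size
    otsu_threshold: int
    degenerate: bool          # True when no foreground could be separated


def preprocess_frame(img: np.ndarray, params: PreprocessParams | None = None) -> PreprocessResult:
    """Full front end: crop/resize → log transform → HSV mask → Otsu → morphology.

    Deterministic; a frame with no in-gamut pixels yields an all-zero mask
    flagged degenerate rather than an error (the caller decides whether an
    empty mask is fatal).
    """
    params = params or PreprocessParams()
    work = crop_and_resize(img, params)
    work = log_transform(work, params)
    masked = hsv_mask(work, params)
    gray = to_gray(masked)
    threshold, binary, degenerate = otsu_binarize(gray)
    cleaned = morph_clean(binary, params)
    if not degenerate and not cleaned.any():
        degenerate = True
    return PreprocessResult(cleaned, threshold, degenerate)
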