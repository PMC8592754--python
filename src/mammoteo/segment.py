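"""Candidate-mass segmentation: color-space handling, Otsu thresholding
and morphological post-processing.

Chromatic inputs are converted RGB -> CIE XYZ, the red and X channels
are normalized pixelwise (R-hat = R / ||(R,G,B)||, X-hat = X / ||(X,Y,Z)||),
each normalized channel is Otsu-thresholded and the two masks are
intersected.  Grayscale inputs (R = G = B would make both normalized
channels constant) are thresholded directly on intensity.  The raw mask
is then hole-filled, opened and closed with a 5x5 structuring element.

The threshold maximizes the between-class variance
``sigma_b^2(t) = w1 w2 (mu1 - mu2)^2`` over a value histogram; ties are
broken toward the lower threshold.  A minimum between-class contrast
guard rejects splits whose class means are too close to mark a mass
(pure texture or field/background splits), returning an empty mask.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy import ndimage

from .preprocess import DegenerateImageError

__all__ = [
    "rgb_to_xyz",
    "normalize_channels",
    "otsu_threshold",
    "otsu_from_counts",
    "fill_holes",
    "opening",
    "closing",
    "identity_se",
    "ones_se",
    "segment",
]

# CIE 1931 RGB -> XYZ, scaled by 1/0.17697 so that Y has unit weight at
# the green primary
_XYZ_MATRIX = (
    np.array(
        [
            [0.49, 0.31, 0.20],
            [0.17697, 0.8124, 0.01063],
            [0.00, 0.01, 0.99],
        ]
    )
    / 0.17697
)


def rgb_to_xyz(image: np.ndarray) -> np.ndarray:
    """Convert an (H, W, 3) RGB image in [0, 1] to CIE XYZ (linear map)."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    return img @ _XYZ_MATRIX.T


def normalize_channels(rgb: np.ndarray, xyz: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Pixelwise chromatic normalization of the R and X channels.

    Zero-norm pixels map to 0 by convention.
    """
    rgb = np.asarray(rgb, dtype=float)
    xyz = np.asarray(xyz, dtype=float)
    if rgb.shape != xyz.shape:
        raise ValueError("rgb and xyz shapes must match")
    rn = np.linalg.norm(rgb, axis=-1)
    xn = np.linalg.norm(xyz, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = np.where(rn > 0, rgb[..., 0] / np.maximum(rn, 1e-300), 0.0)
        xhat = np.where(xn > 0, xyz[..., 0] / np.maximum(xn, 1e-300), 0.0)
    return rhat, xhat


# ---------------------------------------------------------------------------
# Otsu threshold
# ---------------------------------------------------------------------------


def otsu_from_counts(counts: np.ndarray) -> Tuple[int, np.ndarray]:
    """Between-class-variance-maximizing split of an integer histogram.

    Returns ``(k, sigma_b2)`` where the split places bins ``0..k`` in the
    low class and ``k+1..`` in the high class; ties go to the lowest k.
    ``sigma_b2[k]`` is the between-class variance of each split.

    The argmax is decided in exact integer arithmetic: with class count
    ``C1`` and first moment ``S1`` over bins ``0..k``, total count ``N``
    and total moment ``S``,

        sigma_b2(k) = (S1*N - S*C1)^2 / (N^2 * C1 * (N - C1)),

    so candidate splits are compared by cross-multiplying the exact
    integer numerators/denominators.  This makes the selection (and its
    tie-break toward the lower threshold) independent of float rounding.
    """
    arr = np.asarray(counts)
    if arr.ndim != 1 or arr.size < 2:
        raise DegenerateImageError("histogram must be a 1-D array of >= 2 bins")
    ints = np.rint(arr).astype(np.int64)
    if np.any(np.abs(arr - ints) > 1e-9) or np.any(ints < 0):
        raise ValueError("histogram counts must be non-negative integers")
    N = int(ints.sum())
    if N <= 0:
        raise DegenerateImageError("empty histogram")
    S = int(np.sum(ints * np.arange(ints.size, dtype=np.int64)))

    best_k, best_num, best_den = 0, 0, 1  # value = num / den, exact
    c1 = s1 = 0
    for k in range(ints.size - 1):
        c1 += int(ints[k])
        s1 += int(ints[k]) * k
        c2 = N - c1
        if c1 == 0 or c2 == 0:
            num, den = 0, 1
        else:
            a = s1 * N - S * c1
            num, den = a * a, c1 * c2
        if num * best_den > best_num * den:  # strict: ties keep the lower k
            best_k, best_num, best_den = k, num, den
    k = best_k

    # float between-class variance profile for diagnostics/identities
    p = ints / N
    levels = np.arange(ints.size, dtype=float)
    w1 = np.cumsum(p)[:-1]
    w2 = 1.0 - w1
    cmu = np.cumsum(p * levels)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu1 = np.where(w1 > 0, cmu[:-1] / np.maximum(w1, 1e-300), 0.0)
        mu2 = np.where(w2 > 0, (cmu[-1] - cmu[:-1]) / np.maximum(w2, 1e-300), 0.0)
    sigma_b2 = w1 * w2 * (mu1 - mu2) ** 2
    return k, sigma_b2


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Otsu threshold of an intensity image in [0, 1].

    The returned value is the upper edge of the low-class bin; pixels
    strictly above it belong to the foreground class.
    """
    img = np.asarray(values, dtype=float)
    if img.min() == img.max():
        raise DegenerateImageError("constant image: Otsu threshold undefined")
    counts, edges = np.histogram(np.clip(img, 0.0, 1.0), bins=n_bins, range=(0.0, 1.0))
    if np.count_nonzero(counts) < 2:
        raise DegenerateImageError("all values fall in one histogram bin")
    k, _ = otsu_from_counts(counts)
    return float(edges[k + 1])


# ---------------------------------------------------------------------------
# mathematical morphology
# ---------------------------------------------------------------------------


def identity_se(size: int = 5) -> np.ndarray:
    """Diagonal-line (identity-matrix) structuring element."""
    return np.eye(size, dtype=bool)


def ones_se(size: int = 5) -> np.ndarray:
    """Solid square structuring element."""
    return np.ones((size, size), dtype=bool)


def _as_mask(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    return m.astype(bool)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill enclosed background by conditional dilation from the border.

    Grows a background marker inward (``X_k = (X_{k-1} dilate B) & ~A``,
    4-connected) from the image border to a fixed point; background not
    reached this way is a hole and becomes foreground.
    """
    A = _as_mask(mask)
    comp = ~A
    X = np.zeros_like(A)
    X[0, :] = comp[0, :]
    X[-1, :] = comp[-1, :]
    X[:, 0] = comp[:, 0]
    X[:, -1] = comp[:, -1]
    B = ndimage.generate_binary_structure(2, 1)
    while True:
        grown = ndimage.binary_dilation(X, structure=B) & comp
        if np.array_equal(grown, X):
            break
        X = grown
    return A | ~X


def _erode(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    # border_value=1 so that erosion is the exact dual of dilation
    return ndimage.binary_erosion(mask, structure=se, border_value=1)


def _dilate(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    return ndimage.binary_dilation(mask, structure=se, border_value=0)


def opening(mask: np.ndarray, se: np.ndarray | None = None) -> np.ndarray:
    """Morphological opening (erode then dilate); removes speckle smaller
    than the structuring element."""
    se = identity_se() if se is None else np.asarray(se, dtype=bool)
    return _dilate(_erode(_as_mask(mask), se), se)


def closing(mask: np.ndarray, se: np.ndarray | None = None) -> np.ndarray:
    """Morphological closing (dilate then erode); bridges narrow gaps."""
    se = identity_se() if se is None else np.asarray(se, dtype=bool)
    return _erode(_dilate(_as_mask(mask), se), se)


# ---------------------------------------------------------------------------
# assembled segmentation
# ---------------------------------------------------------------------------


def _threshold_mask(values: np.ndarray, n_bins: int, min_contrast: float) -> np.ndarray:
    t = otsu_threshold(values, n_bins=n_bins)
    mask = values > t
    if mask.all() or not mask.any():
        return np.zeros(values.shape, dtype=bool)
    if float(values[mask].mean() - values[~mask].mean()) < min_contrast:
        return np.zeros(values.shape, dtype=bool)
    return mask


def segment(
    image: np.ndarray,
    se: str | np.ndarray = "identity",
    channels: str = "auto",
    n_bins: int = 256,
    min_contrast: float = 0.35,
) -> np.ndarray:
    """Full segmentation: threshold -> fill holes -> open -> close.

    ``channels``: "gray" thresholds intensity, "xyz" uses the normalized
    R-hat/X-hat pair (masks intersected), "auto" picks by input shape.
    ``se``: "identity", "ones" or an explicit boolean array.
    ``min_contrast``: minimum separation of the two Otsu class means for
    a candidate mass to be reported; below it the mask is empty.
    """
    img = np.asarray(image, dtype=float)
    if isinstance(se, str):
        se_arr = {"identity": identity_se(), "ones": ones_se()}[se]
    else:
        se_arr = np.asarray(se, dtype=bool)

    if channels == "auto":
        channels = "xyz" if img.ndim == 3 else "gray"

    if channels == "xyz":
        if img.ndim != 3:
            raise ValueError("xyz channel mode needs an (H, W, 3) image")
        xyz = rgb_to_xyz(img)
        rhat, xhat = normalize_channels(img, xyz)
        mask = _threshold_mask(rhat, n_bins, min_contrast) & _threshold_mask(
            xhat, n_bins, min_contrast
        )
    elif channels == "gray":
        if img.ndim == 3:
            img = img.mean(axis=-1)
        mask = _threshold_mask(img, n_bins, min_contrast)
    else:
        raise ValueError(f"unknown channel mode {channels!r}")

    mask = fill_holes(mask)
    mask = opening(mask, se_arr)
    mask = closing(mask, se_arr)
    return mask
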