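"""Wavelet-subband texture features via the gray-level co-occurrence
matrix (GLCM).

A region of interest is decomposed with a one-level separable 2-D DWT
(Haar by default: orthogonal, so the subbands carry exactly the source
energy and the transform round-trips to machine precision).  Selected
subbands (approximation LL and the vertical-detail HL by default) are
min-max rescaled, quantized to 256 gray levels and summarized by the
GLCM at distance 1, averaged over the four standard angles
{0, 45, 90, 135} degrees.  Five Haralick statistics are reported per
subband, in the fixed column order

    H  (homogeneity)   sum f / (1 + (i-j)^2)
    CR (correlation)   sum (i-mu_i)(j-mu_j) f / (sigma_i sigma_j)
    E  (energy)        sum f^2
    CN (contrast)      sum (i-j)^2 f
    ER (entropy)       -sum f log2 f      (0 log 0 := 0)

Correlation is defined as 0 when either marginal deviation vanishes.
A ``verbatim_formulas`` switch replaces entropy and correlation by the
non-standard printed variants sometimes seen in the applied literature
(entropy without the ``f`` multiplier, correlation with the product
moment ``sum i j f - mu_i mu_j``); the standard Haralick forms are the
default because only they are bounded/dimensionally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pywt
from skimage.feature import graycomatrix

__all__ = [
    "SubbandSet",
    "dwt_decompose",
    "quantize",
    "glcm",
    "haralick_features",
    "extract_features",
    "FEATURE_ORDER",
    "feature_names",
]

FEATURE_ORDER = ("H", "CR", "E", "CN", "ER")

# degrees -> radians for skimage's offset convention
# (row offset = round(d sin a), col offset = round(d cos a))
_ANGLES = {0: 0.0, 45: np.pi / 4, 90: np.pi / 2, 135: 3 * np.pi / 4}


@dataclass
class SubbandSet:
    """One decomposition level: approximation LL plus detail subbands
    LH (horizontal), HL (vertical) and HH (diagonal)."""

    LL: np.ndarray
    LH: np.ndarray
    HL: np.ndarray
    HH: np.ndarray

    def __getitem__(self, name: str) -> np.ndarray:
        return getattr(self, name)


def dwt_decompose(image: np.ndarray, wavelet: str = "haar", levels: int = 1) -> List[SubbandSet]:
    """Separable 2-D DWT; the level-k approximation feeds level k+1.

    Returns one :class:`SubbandSet` per level, coarsest last.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    if min(img.shape) < 2**levels:
        raise ValueError(
            f"image of shape {img.shape} too small for {levels} decomposition level(s)"
        )
    out: List[SubbandSet] = []
    approx = img
    for _ in range(levels):
        approx, (cH, cV, cD) = pywt.dwt2(approx, wavelet)
        out.append(SubbandSet(LL=approx, LH=cH, HL=cV, HH=cD))
    return out


def quantize(values: np.ndarray, levels: int = 256, rescale: bool = True) -> np.ndarray:
    """Quantize to integer gray levels 0..levels-1 (floor rule, the top
    of the range inclusive at the last level).

    With ``rescale`` the value range is first min-max mapped to [0, 1]
    (constant inputs map to level 0); otherwise values are assumed to
    lie in [0, 1] already.
    """
    v = np.asarray(values, dtype=float)
    if rescale:
        lo, hi = float(v.min()), float(v.max())
        v = np.zeros_like(v) if hi <= lo else (v - lo) / (hi - lo)
    q = np.floor(np.clip(v, 0.0, 1.0) * levels).astype(np.int64)
    return np.minimum(q, levels - 1)


def glcm(
    image: np.ndarray,
    d: int = 1,
    angle: int = 0,
    levels: int = 256,
    symmetric: bool = False,
) -> np.ndarray:
    """Normalized co-occurrence matrix of an integer-quantized image.

    ``angle`` must be one of {0, 45, 90, 135} degrees; the pixel pair
    offset is (round(d sin a), round(d cos a)).  Entries sum to 1.
    """
    if angle not in _ANGLES:
        raise ValueError(f"unsupported angle {angle}; choose from {sorted(_ANGLES)}")
    img = np.asarray(image)
    if img.dtype.kind not in "iu":
        raise ValueError("glcm expects an integer-quantized image (see quantize())")
    if img.max() >= levels:
        raise ValueError("image contains gray levels >= levels")
    P = graycomatrix(
        img.astype(np.uint8 if levels <= 256 else np.uint16),
        distances=[d],
        angles=[_ANGLES[angle]],
        levels=levels,
        symmetric=symmetric,
        normed=False,
    )[:, :, 0, 0].astype(float)
    total = P.sum()
    return P / total if total > 0 else P


def haralick_features(P: np.ndarray, verbatim_formulas: bool = False) -> Dict[str, float]:
    """Five texture statistics of a normalized GLCM (see module docs)."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("GLCM must be square")
    total = P.sum()
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError("GLCM must be normalized to sum 1")
    n = P.shape[0]
    i = np.arange(n, dtype=float)[:, None]
    j = np.arange(n, dtype=float)[None, :]

    contrast = float(np.sum((i - j) ** 2 * P))
    energy = float(np.sum(P * P))
    homogeneity = float(np.sum(P / (1.0 + (i - j) ** 2)))

    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = float(np.sum(np.arange(n) * pi))
    mu_j = float(np.sum(np.arange(n) * pj))
    var_i = float(np.sum((np.arange(n) - mu_i) ** 2 * pi))
    var_j = float(np.sum((np.arange(n) - mu_j) ** 2 * pj))
    sd = np.sqrt(var_i * var_j)

    nz = P > 0
    if verbatim_formulas:
        entropy = float(-np.sum(np.log2(P[nz])))
        correlation = 0.0 if sd == 0 else float((np.sum(i * j * P) - mu_i * mu_j) / sd)
    else:
        entropy = float(-np.sum(P[nz] * np.log2(P[nz])))
        correlation = (
            0.0 if sd == 0 else float(np.sum((i - mu_i) * (j - mu_j) * P) / sd)
        )

    return {
        "H": homogeneity,
        "CR": correlation,
        "E": energy,
        "CN": contrast,
        "ER": entropy,
    }


@dataclass
class FeatureConfig:
    wavelet: str = "haar"
    subbands: Tuple[str, ...] = ("LL", "HL")
    levels: int = 256
    distance: int = 1
    angles: Tuple[int, ...] = (0, 45, 90, 135)
    symmetric: bool = False
    verbatim_formulas: bool = False


def feature_names(config: FeatureConfig | None = None) -> List[str]:
    cfg = config or FeatureConfig()
    return [f"{sb}_{f}" for sb in cfg.subbands for f in FEATURE_ORDER]


def extract_features(
    image: np.ndarray,
    mask: np.ndarray,
    config: FeatureConfig | None = None,
) -> np.ndarray:
    """Feature vector of the masked region: per configured subband, the
    five GLCM statistics averaged over the four angles at distance 1.

    The image is cropped to the mask bounding box before decomposition.
    Raises for an empty mask.
    """
    cfg = config or FeatureConfig()
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask).astype(bool)
    if img.shape != m.shape:
        raise ValueError("image and mask shapes must match")
    if not m.any():
        raise ValueError("empty mask: no region to extract features from")
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    crop = img[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    # pad tiny crops so one decomposition level is well defined
    if min(crop.shape) < 2:
        crop = np.pad(crop, ((0, max(0, 2 - crop.shape[0])), (0, max(0, 2 - crop.shape[1]))), mode="edge")

    bands = dwt_decompose(crop, wavelet=cfg.wavelet, levels=1)[0]
    out: List[float] = []
    for sb in cfg.subbands:
        q = quantize(bands[sb], levels=cfg.levels, rescale=True)
        acc = {f: 0.0 for f in FEATURE_ORDER}
        used = 0
        for ang in cfg.angles:
            P = glcm(q, d=cfg.distance, angle=ang, levels=cfg.levels, symmetric=cfg.symmetric)
            if P.sum() == 0:  # no pixel pairs at this offset (degenerate crop)
                continue
            feats = haralick_features(P, verbatim_formulas=cfg.verbatim_formulas)
            for f in FEATURE_ORDER:
                acc[f] += feats[f]
            used += 1
        if used == 0:
            raise ValueError("region too small for any co-occurrence pair")
        out.extend(acc[f] / used for f in FEATURE_ORDER)
    return np.asarray(out, dtype=float)
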