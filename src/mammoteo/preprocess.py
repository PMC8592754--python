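"""Contrast enhancement and Wang-Mendel fuzzy-rule noise reduction.

``contrast_stretch`` performs a full-range linear stretch
``y = (x - min) / (max - min)`` routed through a 65 536-entry lookup
table (16-bit quantization of the input axis), so repeated application
is the identity up to LUT quantization.

The Wang-Mendel (WM) stage learns a fuzzy rule base from a
(noisy, reference) image pair and applies it pixelwise:

1. each variable's range [0, 1] is partitioned into K overlapping
   triangular fuzzy sets (a Ruspini partition: memberships sum to 1);
2. every training pixel proposes one rule, antecedents = (center value,
   3x3 neighborhood mean) of the noisy image, consequent = the reference
   value, each fuzzified to its maximal-membership label;
3. the rule's degree is the product of the three memberships;
4. among rules sharing an antecedent tuple only the max-degree rule
   survives;
5. inference replaces each pixel by the strength-weighted centroid of
   the firing rules' consequent sets (product inference, centroid
   defuzzification); pixels firing no rule pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "DegenerateImageError",
    "contrast_stretch",
    "FuzzyRuleBase",
    "wm_build_rules",
    "wm_denoise",
]

LUT_SIZE = 65_536


class DegenerateImageError(ValueError):
    """Raised for inputs the operation cannot meaningfully process."""


def _check_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale array")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return img


def contrast_stretch(image: np.ndarray) -> np.ndarray:
    """Linear full-range contrast stretch through a 16-bit lookup table.

    Raises :class:`DegenerateImageError` for a constant image (the
    stretch denominator would vanish).
    """
    img = _check_gray(image)
    lo = float(img.min())
    hi = float(img.max())
    if hi <= lo:
        raise DegenerateImageError("constant image: contrast stretch undefined")
    # quantize input values onto the 16-bit LUT axis, then map linearly
    idx = np.rint(np.clip(img, 0.0, 1.0) * (LUT_SIZE - 1)).astype(np.int64)
    lo_idx = int(round(lo * (LUT_SIZE - 1)))
    hi_idx = int(round(hi * (LUT_SIZE - 1)))
    axis = np.arange(LUT_SIZE, dtype=float)
    lut = np.clip((axis - lo_idx) / max(hi_idx - lo_idx, 1), 0.0, 1.0)
    return lut[idx]


# ---------------------------------------------------------------------------
# Wang-Mendel rules
# ---------------------------------------------------------------------------


@dataclass
class FuzzyRuleBase:
    """Triangular-partition rule base.

    ``rules`` maps an antecedent label pair (center label, mean label)
    to ``(consequent label, degree)``; at most one rule per antecedent.
    """

    k: int
    rules: Dict[Tuple[int, int], Tuple[int, float]]

    def __len__(self) -> int:
        return len(self.rules)

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.k)


def _tri_membership(x: np.ndarray, label: int, k: int) -> np.ndarray:
    """Membership of ``x`` in triangular set ``label`` of a K-set Ruspini
    partition of [0, 1] with centers at j/(K-1)."""
    scaled = np.asarray(x, dtype=float) * (k - 1)
    return np.clip(1.0 - np.abs(scaled - label), 0.0, 1.0)


def _nearest_label(x: np.ndarray, k: int) -> np.ndarray:
    """Maximal-membership label: the nearest partition center."""
    return np.clip(np.rint(np.asarray(x, dtype=float) * (k - 1)), 0, k - 1).astype(int)


def _local_mean(img: np.ndarray) -> np.ndarray:
    return ndimage.uniform_filter(img, size=3, mode="reflect")


def wm_build_rules(noisy: np.ndarray, reference: np.ndarray, k_partitions: int = 7) -> FuzzyRuleBase:
    """Learn a WM rule base from a (noisy, reference) image pair."""
    noisy = _check_gray(noisy)
    reference = _check_gray(reference)
    if noisy.shape != reference.shape:
        raise ValueError("noisy and reference images must share a shape")
    if k_partitions < 2:
        raise ValueError("need at least 2 fuzzy partitions")
    k = k_partitions

    center = np.clip(noisy, 0.0, 1.0).ravel()
    mean = np.clip(_local_mean(noisy), 0.0, 1.0).ravel()
    ref = np.clip(reference, 0.0, 1.0).ravel()

    lc = _nearest_label(center, k)
    lm = _nearest_label(mean, k)
    lo = _nearest_label(ref, k)
    # membership at the chosen (nearest-center) label
    mu_c = np.clip(1.0 - np.abs(center * (k - 1) - lc), 0.0, 1.0)
    mu_m = np.clip(1.0 - np.abs(mean * (k - 1) - lm), 0.0, 1.0)
    mu_o = np.clip(1.0 - np.abs(ref * (k - 1) - lo), 0.0, 1.0)
    degree = mu_c * mu_m * mu_o

    # keep the max-degree rule per antecedent tuple
    key = lc * k + lm
    order = np.lexsort((degree, key))  # within each key, ascending degree
    key_s, lo_s, deg_s = key[order], lo[order], degree[order]
    last = np.r_[key_s[1:] != key_s[:-1], True]  # last (max-degree) per key
    rules: Dict[Tuple[int, int], Tuple[int, float]] = {}
    for kk, cons, deg in zip(key_s[last], lo_s[last], deg_s[last]):
        rules[(int(kk) // k, int(kk) % k)] = (int(cons), float(deg))
    return FuzzyRuleBase(k=k, rules=rules)


def wm_denoise(image: np.ndarray, rules: FuzzyRuleBase) -> np.ndarray:
    """Apply a WM rule base to an image (product inference, centroid
    defuzzification); pixels with no firing rule pass through."""
    img = _check_gray(image)
    if len(rules) == 0:
        raise ValueError("rule base is empty")
    k = rules.k
    center = np.clip(img, 0.0, 1.0)
    mean = np.clip(_local_mean(img), 0.0, 1.0)
    centers = rules.centers

    num = np.zeros_like(center)
    den = np.zeros_like(center)
    for (lc, lm), (cons, _deg) in rules.rules.items():
        strength = _tri_membership(center, lc, k) * _tri_membership(mean, lm, k)
        num += strength * centers[cons]
        den += strength
    out = np.where(den > 0, num / np.maximum(den, 1e-300), img)
    return np.clip(out, 0.0, 1.0)
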