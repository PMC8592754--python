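"""Synthetic mammographic phantoms with ground truth.

Each phantom emulates a screening-film mammogram at a reduced scale: a
dark detector background, an elliptical breast field with a smooth
illumination gradient, and optionally a bright mass.  The mass has a
flat-topped radial profile (constant contrast inside a core radius with
a Gaussian shoulder), so a global threshold anywhere on the shoulder
recovers nearly the same region — the ground-truth mask marks pixels
whose mass profile exceeds half the nominal contrast.

The benign/malignant class signal lives in the mass texture, because
the downstream features are co-occurrence statistics: malignant masses
carry short-correlation-length, high-amplitude internal texture
(rough), benign masses long-correlation-length, low-amplitude texture
(smooth).  Pixel noise is i.i.d. Gaussian.  Everything is clipped to
[0, 1] and fully determined by the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["PhantomSpec", "PhantomSpecError", "generate_phantom", "generate_dataset"]

BENIGN, MALIGNANT = "benign", "malignant"


class PhantomSpecError(ValueError):
    """Inconsistent phantom specification (e.g. mass outside the breast)."""


@dataclass
class PhantomSpec:
    """Parameters of one phantom; lengths are in pixels of ``size``."""

    size: Tuple[int, int] = (128, 128)
    ellipse_axes: Tuple[float, float] = (0.42, 0.52)  # fractions of H, W
    ellipse_angle: float = 0.0  # radians
    background: float = 0.05
    field_level: float = 0.15
    gradient_amplitude: float = 0.06
    mass_present: bool = True
    mass_center: Optional[Tuple[float, float]] = None  # defaults to image center
    mass_radius: float = 10.0  # flat core radius
    mass_edge: float = 2.5  # Gaussian shoulder width
    mass_contrast: float = 0.5
    texture_scale: float = 3.0  # correlation length of internal texture
    texture_amplitude: float = 0.03
    noise_sigma: float = 0.02
    label: str = BENIGN
    seed: int = 0


def _ellipse_field(spec: PhantomSpec) -> Tuple[np.ndarray, np.ndarray]:
    h, w = spec.size
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ay, ax = spec.ellipse_axes[0] * h, spec.ellipse_axes[1] * w
    ct, st = np.cos(spec.ellipse_angle), np.sin(spec.ellipse_angle)
    u = (yy - cy) * ct + (xx - cx) * st
    v = -(yy - cy) * st + (xx - cx) * ct
    r2 = (u / ay) ** 2 + (v / ax) ** 2
    inside = r2 <= 1.0
    # smooth illumination gradient across the field plus a soft radial falloff
    grad = spec.gradient_amplitude * (u / ay + 0.5 * (1.0 - r2))
    return inside, grad


def _mass_profile(spec: PhantomSpec) -> np.ndarray:
    h, w = spec.size
    cy, cx = spec.mass_center if spec.mass_center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - cy, xx - cx)
    shoulder = np.maximum(r - spec.mass_radius, 0.0)
    return spec.mass_contrast * np.exp(-0.5 * (shoulder / spec.mass_edge) ** 2)


def _correlated_noise(shape: Tuple[int, int], scale: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=scale, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def generate_phantom(spec: PhantomSpec) -> Tuple[np.ndarray, np.ndarray, str]:
    """Render one phantom.

    Returns ``(image, truth_mask, label)``; the mask marks pixels whose
    mass profile exceeds half the nominal contrast (empty when no mass).
    """
    if spec.label not in (BENIGN, MALIGNANT):
        raise PhantomSpecError(f"unknown label {spec.label!r}")
    rng = np.random.default_rng(spec.seed)
    inside, grad = _ellipse_field(spec)
    img = np.full(spec.size, spec.background, dtype=float)
    img[inside] = spec.field_level + grad[inside]

    mask = np.zeros(spec.size, dtype=bool)
    if spec.mass_present:
        profile = _mass_profile(spec)
        mask = profile > spec.mass_contrast / 2.0
        if np.any(mask & ~inside):
            raise PhantomSpecError("mass extends outside the breast ellipse")
        img = img + profile * inside
        texture = _correlated_noise(spec.size, spec.texture_scale, rng)
        img = img + spec.texture_amplitude * texture * (profile / max(spec.mass_contrast, 1e-12))

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=spec.size)
    return np.clip(img, 0.0, 1.0), mask, spec.label


def _class_spec(label: str) -> dict:
    # texture separation between the classes, in the measured (GLCM) space
    if label == MALIGNANT:
        return {"texture_scale": 1.2, "texture_amplitude": 0.10}
    return {"texture_scale": 3.0, "texture_amplitude": 0.03}


def generate_dataset(
    n: int,
    class_balance: float = 0.5,
    seed: int = 0,
    size: Tuple[int, int] = (128, 128),
    mass_contrast: float = 0.5,
    noise_sigma: float = 0.02,
) -> Tuple[List[Tuple[np.ndarray, np.ndarray, str]], pd.DataFrame]:
    """Reproducible phantom cohort.

    ``class_balance`` is the malignant fraction; per-sample seeds are
    drawn once from the master seed so the cohort is reproducible and
    individual samples are independent.  Returns the samples and a
    manifest table (index, label, seed and geometry per sample).
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    n_mal = int(round(n * class_balance))
    labels = [MALIGNANT] * n_mal + [BENIGN] * (n - n_mal)
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n)
    h, w = size

    samples, rows = [], []
    for i, (label, s) in enumerate(zip(labels, child_seeds)):
        geo = np.random.default_rng(s)
        radius = geo.uniform(8.0, 12.0) * min(h, w) / 128.0
        # keep the mass core + shoulder well inside the ellipse
        cy = (h - 1) / 2.0 + geo.uniform(-0.12, 0.12) * h
        cx = (w - 1) / 2.0 + geo.uniform(-0.12, 0.12) * w
        spec = PhantomSpec(
            size=size,
            mass_center=(cy, cx),
            mass_radius=radius,
            mass_contrast=mass_contrast,
            noise_sigma=noise_sigma,
            label=label,
            seed=int(s),
            **_class_spec(label),
        )
        samples.append(generate_phantom(spec))
        rows.append(
            {
                "index": i,
                "label": label,
                "seed": int(s),
                "mass_cy": cy,
                "mass_cx": cx,
                "mass_radius": radius,
                "mass_contrast": mass_contrast,
                "noise_sigma": noise_sigma,
            }
        )
    return samples, pd.DataFrame(rows)
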