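"""Image and table I/O.

Images are exchanged as 8-bit PGM (the plain binary dialect used by
classic mammography archives) or PNG and carried in memory as float
arrays in [0, 1].  Masks are written as 0/255 PNG.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = ["ImageReadError", "read_image", "write_image", "write_mask", "read_mask",
           "save_model", "load_model"]


class ImageReadError(IOError):
    """Unsupported, corrupt or truncated image file."""


def read_image(path: str | Path) -> np.ndarray:
    """Read a PGM/PNG image, scaled to [0, 1].

    Grayscale files return (H, W); color files return (H, W, 3).
    """
    path = Path(path)
    if not path.exists():
        raise ImageReadError(f"no such file: {path}")
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("I;16", "I"):
                arr = np.asarray(im, dtype=float) / 65535.0
            elif im.mode in ("L", "P"):
                arr = np.asarray(im.convert("L"), dtype=float) / 255.0
            else:
                arr = np.asarray(im.convert("RGB"), dtype=float) / 255.0
    except (UnidentifiedImageError, OSError, SyntaxError, ValueError) as exc:
        raise ImageReadError(f"cannot read image {path}: {exc}") from exc
    return np.clip(arr, 0.0, 1.0)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] image as 8-bit grayscale (2-D) or RGB (3-D) file."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    data = np.rint(arr * 255.0).astype(np.uint8)
    mode = "L" if data.ndim == 2 else "RGB"
    Image.fromarray(data, mode=mode).save(Path(path))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    data = (np.asarray(mask).astype(bool) * np.uint8(255))
    Image.fromarray(data, mode="L").save(Path(path))


def read_mask(path: str | Path) -> np.ndarray:
    return read_image(path) > 0.5


def save_model(path: str | Path, spec, weights: np.ndarray, scaler=None) -> None:
    """Serialize a classifier as architecture fields + flat weight list,
    with the optional (mean, std) feature scaler fitted on training data."""
    from dataclasses import asdict

    payload = {"spec": asdict(spec), "weights": np.asarray(weights, dtype=float).tolist()}
    if scaler is not None:
        mu, sd = scaler
        payload["scaler"] = {"mean": np.asarray(mu).tolist(), "std": np.asarray(sd).tolist()}
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path):
    """Returns (spec, weights, scaler); scaler is (mean, std) or None."""
    from .network import NetworkSpec

    payload = json.loads(Path(path).read_text())
    spec = NetworkSpec(**payload["spec"])
    weights = np.asarray(payload["weights"], dtype=float)
    scaler = None
    if "scaler" in payload:
        scaler = (
            np.asarray(payload["scaler"]["mean"], dtype=float),
            np.asarray(payload["scaler"]["std"], dtype=float),
        )
    return spec, weights, scaler
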