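"""Grayscale image and mask I/O.

Images are read as 2D float arrays in [0, 1] (8-bit values divided by 255;
color inputs are averaged to luminance).  Masks are written as 8-bit PNG with
foreground 255 / background 0; on reading, any pixel > 0 is foreground unless
the polarity heuristic (foreground should be the majority class in the
central window) says the file uses the inverted display convention.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_gray", "write_gray", "read_mask", "write_mask"]


def read_gray(path: str | Path) -> np.ndarray:
    """Read a grayscale image as floats in [0, 1]."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    arr = arr.astype(float)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)


def write_gray(path: str | Path, image: np.ndarray) -> None:
    """Write a float image, linearly rescaled to use the full 8-bit range."""
    image = np.asarray(image, dtype=float)
    lo, hi = float(image.min()), float(image.max())
    scaled = np.zeros_like(image) if hi <= lo else (image - lo) / (hi - lo)
    iio.imwrite(Path(path), np.round(scaled * 255).astype(np.uint8))


def read_mask(path: str | Path, polarity: str = "auto") -> np.ndarray:
    """Read a binary mask.

    ``polarity``: ``"white"`` (pixel > 0 is foreground), ``"black"``
    (inverted display convention), or ``"auto"`` — pick the polarity whose
    foreground dominates the central quarter window of the image.
    """
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    mask = arr > 0
    if polarity == "black":
        return ~mask
    if polarity == "white":
        return mask
    h, w = mask.shape
    center = mask[h // 2 - h // 8 : h // 2 + h // 8 + 1, w // 2 - w // 8 : w // 2 + w // 8 + 1]
    return mask if center.mean() >= 0.5 else ~mask


def write_mask(path: str | Path, mask: np.ndarray, invert_display: bool = False) -> None:
    """Write a boolean mask as 8-bit PNG; ``invert_display`` renders the ROI
    black on white for figure-style display."""
    mask = np.asarray(mask, dtype=bool)
    if invert_display:
        mask = ~mask
    iio.imwrite(Path(path), (mask.astype(np.uint8)) * 255)
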