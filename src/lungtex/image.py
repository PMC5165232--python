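"""Quantized grayscale image container and PNG/PGM I/O.

All texture operations work on a :class:`GrayImage`: a rectangular grid of
integer gray levels in ``[0, G-1]`` where ``G`` is the number of quantization
bins.  8-bit images are reduced to ``G`` uniform bins before any second-order
statistic is computed so that run-length and co-occurrence matrices stay
dense on small regions of interest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image as _PILImage

DEFAULT_GRAY_LEVELS = 8


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grid of integer gray levels with a known quantization depth.

    Parameters
    ----------
    pixels
        2-D integer array; every value must lie in ``[0, gray_levels - 1]``.
    gray_levels
        Number of quantization bins ``G``.
    """

    pixels: np.ndarray
    gray_levels: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("image must be 2-D with at least 2 rows and 2 columns")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("pixel values must be integers")
        if self.gray_levels < 1:
            raise ValueError("gray_levels must be positive")
        if px.min() < 0 or px.max() >= self.gray_levels:
            raise ValueError("pixel values must lie in [0, gray_levels - 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def n_pixels(self) -> int:
        return self.pixels.size


def quantize(raw: np.ndarray, gray_levels: int = DEFAULT_GRAY_LEVELS,
             max_value: int = 255) -> GrayImage:
    """Reduce an 8-bit (or ``[0, max_value]``) image to ``gray_levels`` uniform bins.

    Bin edges partition ``[0, max_value]`` evenly; the mapping is
    ``level = floor(pixel * G / (max_value + 1))`` and is deterministic.
    """
    raw = np.asarray(raw)
    if raw.min() < 0 or raw.max() > max_value:
        raise ValueError(f"raw values must lie in [0, {max_value}]")
    levels = (raw.astype(np.int64) * gray_levels) // (max_value + 1)
    return GrayImage(levels.astype(np.intp), gray_levels)


def load_image(path: str | Path, gray_levels: int | None = DEFAULT_GRAY_LEVELS) -> GrayImage:
    """Load an 8-bit grayscale PNG or PGM file.

    With ``gray_levels=None`` the full 8-bit depth (256 levels) is kept;
    otherwise the image is quantized to the requested number of bins.
    """
    with _PILImage.open(path) as img:
        arr = np.asarray(img.convert("L"), dtype=np.intp)
    if gray_levels is None:
        return GrayImage(arr, 256)
    return quantize(arr, gray_levels)


def save_image(image: np.ndarray | GrayImage, path: str | Path) -> None:
    """Write a grayscale or binary array as 8-bit PNG/PGM (format from suffix)."""
    if isinstance(image, GrayImage):
        # stretch quantized levels back onto [0, 255] for visibility
        arr = image.pixels
        scale = 255 // max(image.gray_levels - 1, 1)
        arr = (arr * scale).astype(np.uint8)
    else:
        arr = np.asarray(image)
        if arr.dtype == bool or arr.max(initial=0) <= 1:
            arr = (arr.astype(np.uint8)) * 255
        else:
            arr = arr.astype(np.uint8)
    _PILImage.fromarray(arr, mode="L").save(path)
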