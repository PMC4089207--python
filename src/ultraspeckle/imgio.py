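"""Grayscale image container, file I/O, and histogram equalization.

Intensities are carried as float64 in the nominal 8-bit range [0, 255];
quantization to uint8 happens only when an image is written to disk, so
repeated filtering passes do not accumulate rounding error.

Pixel (r, c) addresses row r (top-down) and column c (left-right); the x
axis is the column axis and the y axis is the row axis, matching the usual
image-processing convention for derivatives and eigenvectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["GrayImage", "read_gray", "write_gray", "equalize"]

# Rec. 601 luma weights for multi-channel inputs.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayImage:
    """A single-channel image: 2D float64 intensities in [0, 255]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"expected a non-empty 2D array, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite values")
        if px.min() < 0.0 or px.max() > 255.0:
            raise ValueError(
                f"intensities must lie in [0, 255], got [{px.min()}, {px.max()}]"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def asarray(self) -> np.ndarray:
        """Return the underlying float64 array (a defensive copy)."""
        return self.pixels.copy()


def read_gray(path: str | Path) -> GrayImage:
    """Read a PNG/PGM/TIFF image as a :class:`GrayImage`.

    Multi-channel inputs are converted to luminance with Rec. 601 weights
    (0.299 R + 0.587 G + 0.114 B); an alpha channel, if present, is dropped.

    Raises
    ------
    IOError
        If the file is missing or cannot be decoded.
    ValueError
        If the decoded image has zero size.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        raw = iio.imread(path)
    except Exception as exc:  # decoder failures (truncated files etc.)
        raise IOError(f"cannot decode image {path}: {exc}") from exc
    arr = np.asarray(raw, dtype=np.float64)
    if arr.ndim == 3:
        if arr.shape[2] >= 3:
            arr = arr[:, :, :3] @ _LUMA
        else:
            arr = arr[:, :, 0]
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"not a usable 2D image: shape {arr.shape}")
    # 16-bit sources are rescaled into the nominal 8-bit range.
    if arr.max() > 255.0:
        arr = arr * (255.0 / 65535.0)
    return GrayImage(np.clip(arr, 0.0, 255.0))


def write_gray(img: GrayImage, path: str | Path) -> None:
    """Write an image to disk as 8-bit (format chosen by extension, PNG default)."""
    path = Path(path)
    data = np.clip(np.rint(img.pixels), 0, 255).astype(np.uint8)
    iio.imwrite(path, data)


def equalize(img: GrayImage) -> GrayImage:
    """Classical 256-bin CDF histogram equalization.

    Intensities are binned by rounding to the nearest integer level and
    remapped through ``round(255 * (cdf(v) - cdf_min) / (1 - cdf_min))``
    where ``cdf_min`` is the CDF value of the lowest occupied bin.  The
    mapping is monotone non-decreasing.  A single-valued image is returned
    unchanged (the mapping would be degenerate).
    """
    levels = np.clip(np.rint(img.pixels), 0, 255).astype(np.intp)
    hist = np.bincount(levels.ravel(), minlength=256)
    cdf = np.cumsum(hist) / levels.size
    occupied = np.flatnonzero(hist)
    cdf_min = cdf[occupied[0]]
    if cdf_min >= 1.0:  # single-valued image
        return GrayImage(img.pixels.copy())
    lut = np.rint(255.0 * (cdf - cdf_min) / (1.0 - cdf_min))
    return GrayImage(lut[levels])
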