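"""The Micrograph container and TIFF round-tripping.

A micrograph is a single-channel 2D intensity image with a physical pixel
size.  Pixels are stored as a float array internally (background subtraction
produces non-integer values) but written to disk at the declared bit depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import tifffile

#: Default physical pixel size, um/px, for a 100x/1.4 NA objective on a
#: typical sCMOS sensor.
DEFAULT_PIXEL_SIZE_UM = 0.065


@dataclass
class Micrograph:
    """Single-channel 2D intensity image plus pixel-size metadata.

    Parameters
    ----------
    pixels
        2D array of finite, non-negative intensities.
    bit_depth
        8 or 16; the quantization used when writing TIFF.
    pixel_size
        Physical pixel size in micrometres per pixel.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D image, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 16 or self.pixels.shape[1] < 16:
            raise ValueError(f"image too small: {self.pixels.shape}, need >= (16, 16)")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite pixels")
        if self.pixels.min() < 0:
            raise ValueError("image contains negative pixels")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1

    def quantized(self) -> np.ndarray:
        """Pixels rounded and clipped to the integer range of ``bit_depth``."""
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        return np.clip(np.round(self.pixels), 0, self.max_value).astype(dtype)

    def write_tiff(self, path: Union[str, Path]) -> None:
        tifffile.imwrite(
            str(path),
            self.quantized(),
            resolution=(1.0 / self.pixel_size, 1.0 / self.pixel_size),
            metadata={"unit": "um", "pixel_size_um": self.pixel_size},
        )


def read_tiff(
    path: Union[str, Path],
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
) -> list[Micrograph]:
    """Read a single- or multi-page grayscale TIFF as a list of micrographs."""
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a grayscale TIFF stack, got shape {arr.shape}")
    bit_depth = 8 if arr.dtype.itemsize == 1 else 16
    return [Micrograph(page.astype(float), bit_depth, pixel_size) for page in arr]
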