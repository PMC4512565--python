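"""2-D intensity rasters and their file formats.

The whole pipeline operates on :class:`ImageGrid`: a 2-D array of
non-negative (for raw mammograms) intensities plus the acquisition bit depth
and an optional aligned binary mask marking the breast tissue.  Coordinates
follow image convention: ``x`` is the column index, ``y`` the row index,
both 0-based; the pixel spacing is 1.0 unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image


@dataclass
class ImageGrid:
    """A 2-D intensity raster with bit depth and an optional tissue mask."""

    pixels: np.ndarray
    bit_depth: int = 12
    mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not 1 <= self.bit_depth <= 32:
            raise ValueError(f"unsupported bit depth {self.bit_depth}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape:
                raise ValueError("mask shape must match pixels shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_value(self) -> int:
        """Largest representable intensity, ``2**bit_depth - 1``."""
        return 2**self.bit_depth - 1

    def masked_values(self) -> np.ndarray:
        """Flat array of pixel values inside the mask (all pixels if none)."""
        if self.mask is None:
            return self.pixels.ravel()
        return self.pixels[self.mask]

    def with_pixels(self, pixels: np.ndarray, mask: np.ndarray | None = None) -> "ImageGrid":
        """New grid sharing this grid's bit depth (and mask unless overridden)."""
        return ImageGrid(pixels, self.bit_depth, self.mask if mask is None else mask)

    def copy(self) -> "ImageGrid":
        return ImageGrid(
            self.pixels.copy(),
            self.bit_depth,
            None if self.mask is None else self.mask.copy(),
        )


def read_image(path: str | Path, bit_depth: int = 12) -> ImageGrid:
    """Read an 8/16-bit grayscale TIFF or PNG into an :class:`ImageGrid`."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:  # collapse accidental RGB
        arr = arr[..., 0]
    return ImageGrid(arr.astype(np.float64), bit_depth=bit_depth)


def write_image(image: ImageGrid, path: str | Path) -> Path:
    """Write an image as 16-bit grayscale TIFF/PNG or 32-bit float TIFF.

    Integer-valued images fitting 16 bits are stored as ``uint16``; anything
    else (filter outputs, subtraction maps with fractional values) is stored
    as 32-bit float TIFF.
    """
    path = Path(path)
    px = image.pixels
    integral = np.allclose(px, np.round(px)) and px.min() >= 0 and px.max() <= 65535
    if path.suffix.lower() == ".png":
        if not integral:
            raise ValueError("PNG output requires integer intensities in [0, 65535]")
        Image.fromarray(np.round(px).astype(np.uint16)).save(path)
    elif integral:
        tifffile.imwrite(path, np.round(px).astype(np.uint16))
    else:
        tifffile.imwrite(path, px.astype(np.float32))
    return path


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit PNG (0/255)."""
    path = Path(path)
    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(path)
    return path
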