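"""Automatic breast-tissue segmentation.

The breast is the single large bright blob in a mammogram; everything else
is detector background noise plus occasional labels/artifacts.  Segmentation
is therefore: estimate the background noise level, threshold the image five
noise standard deviations above the background level, close small holes
with a 3x3 structuring element, and keep the largest 8-connected component.
No attempt is made to remove the pectoral muscle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import ImageGrid

#: multiplier applied to the noise standard deviation for the initial threshold
NOISE_SD_MULTIPLIER = 5.0
#: width in pixels of the border strip used to sample the background
BORDER_STRIP_WIDTH = 20
_MAD_TO_SD = 1.4826  # consistency factor for Gaussian noise


class NoTissueError(ValueError):
    """Raised when thresholding finds no breast tissue at all."""


@dataclass
class SegmentationResult:
    """Mask plus the noise statistics that produced it.

    ``image`` is the input with every pixel outside the final mask set to 0.
    """

    mask: np.ndarray
    noise_sd: float
    threshold: float
    n_components_before_selection: int
    image: ImageGrid


def _background_strip(pixels: np.ndarray, width: int = BORDER_STRIP_WIDTH) -> np.ndarray:
    """Border strip on the chest-wall-opposite side.

    The chest wall side of a mammogram is filled with tissue, the opposite
    vertical border with background; whichever 20-column strip has the lower
    median intensity is the background one.
    """
    width = min(width, pixels.shape[1])
    left = pixels[:, :width]
    right = pixels[:, -width:]
    return left if np.median(left) <= np.median(right) else right


def estimate_background_noise(image: ImageGrid) -> float:
    """Robust background noise SD: 1.4826 x MAD over the background strip."""
    if image.pixels.size == 0:
        raise ValueError("empty image")
    strip = _background_strip(image.pixels)
    med = np.median(strip)
    return float(_MAD_TO_SD * np.median(np.abs(strip - med)))


def segment_breast(
    image: ImageGrid, sd_multiplier: float = NOISE_SD_MULTIPLIER
) -> SegmentationResult:
    """Threshold at background + 5 sigma, close 3x3, keep the largest component."""
    pixels = image.pixels
    if pixels.size == 0:
        raise ValueError("empty image")
    strip = _background_strip(pixels)
    background = float(np.median(strip))
    noise_sd = float(_MAD_TO_SD * np.median(np.abs(strip - background)))
    threshold = background + sd_multiplier * noise_sd
    initial = pixels > threshold
    if not initial.any():
        raise NoTissueError(f"no pixels above threshold {threshold:.3g}; no tissue found")
    # binary closing (dilate then erode) with a full 3x3 element; pad so the
    # image border does not erode the mask
    padded = np.pad(initial, 2, mode="constant", constant_values=False)
    closed = ndimage.binary_closing(padded, structure=np.ones((3, 3), bool))[2:-2, 2:-2]
    closed |= initial  # closing never removes thresholded tissue
    labels, n_components = ndimage.label(closed, structure=np.ones((3, 3), int))
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == int(np.argmax(sizes))
    cleaned = ImageGrid(np.where(mask, pixels, 0.0), image.bit_depth, mask)
    return SegmentationResult(
        mask=mask,
        noise_sd=noise_sd,
        threshold=float(threshold),
        n_components_before_selection=int(n_components),
        image=cleaned,
    )
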