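"""Enhancement filters and texture maps.

Four operators are applied to every raw and subtraction image:

* MoF — morphological high-frequency enhancement, the image minus its
  grayscale erosion by a flat 5x5 element; enhances fiber-like structures.
* LoG — Gaussian smoothing followed by a 3x3 discrete Laplacian; enhances
  high-frequency intensity changes (signed output).
* LSD — local standard deviation over a 3x3 neighborhood; bright where the
  signal varies, black over flat intensities.
* LFD — local fractal dimension by the triangular prism surface area
  method evaluated at three window scales; higher where fine structure
  repeats across scales.  Values lie in [2, 3].

All windowed operators use replicate (edge-value) padding so that mask
edges do not inject artificial gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import ImageGrid

#: 3x3 discrete Laplacian stencil (4-neighbor)
LAPLACIAN_3X3 = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


@dataclass
class FilterConfig:
    """Window sizes (pixels) for the four operators."""

    mof_element_size: int = 5
    log_sigma: float = 2.0
    lsd_window: int = 3
    lfd_scales: tuple[int, int, int] = (3, 5, 9)
    boundary_mode: str = "replicate"

    def __post_init__(self) -> None:
        if self.log_sigma <= 0:
            raise ValueError("log_sigma must be positive")
        scales = tuple(self.lfd_scales)
        if len(scales) != 3 or list(scales) != sorted(set(scales)):
            raise ValueError("lfd_scales must be three strictly increasing window sizes")
        if any(s < 2 for s in scales):
            raise ValueError("lfd window sizes must be at least 2")
        self.lfd_scales = scales
        if self.boundary_mode != "replicate":
            raise ValueError("only replicate boundary handling is supported")


def mof(image: ImageGrid, cfg: FilterConfig | None = None) -> ImageGrid:
    """Morphological high-frequency enhancement: I - (I erode B), flat 5x5 B."""
    cfg = cfg or FilterConfig()
    eroded = ndimage.grey_erosion(
        image.pixels, size=(cfg.mof_element_size, cfg.mof_element_size), mode="nearest"
    )
    return image.with_pixels(image.pixels - eroded)


def log_filter(image: ImageGrid, cfg: FilterConfig | None = None) -> ImageGrid:
    """Laplacian of Gaussian: Gaussian blur then the 3x3 discrete Laplacian."""
    cfg = cfg or FilterConfig()
    smoothed = ndimage.gaussian_filter(image.pixels, sigma=cfg.log_sigma, mode="nearest")
    lap = ndimage.correlate(smoothed, LAPLACIAN_3X3, mode="nearest")
    return image.with_pixels(lap)


def local_std(image: ImageGrid, cfg: FilterConfig | None = None) -> ImageGrid:
    """Per-pixel standard deviation over the 3x3 neighborhood."""
    cfg = cfg or FilterConfig()
    size = (cfg.lsd_window, cfg.lsd_window)
    m1 = ndimage.uniform_filter(image.pixels, size=size, mode="nearest")
    m2 = ndimage.uniform_filter(image.pixels**2, size=size, mode="nearest")
    var = np.clip(m2 - m1**2, 0.0, None)
    return image.with_pixels(np.sqrt(var))


def _prism_surface_area(pixels: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel triangular prism surface area over a ``window``-sized cell.

    The cell is the square of side d = window - 1 centered on the pixel (for
    even windows the half-offsets round outward).  Its four corner
    intensities a, b, c, d plus the center e = (a+b+c+d)/4 define four 3-D
    triangles whose areas are summed, then normalized by the planar cell
    area d^2 so a flat surface scores 1 at every scale.
    """
    lo = (window - 1) // 2
    hi = window - 1 - lo
    d = float(window - 1)
    padded = np.pad(pixels.astype(np.float64), (lo, hi), mode="edge")
    h, w = pixels.shape
    a = padded[0:h, 0:w]            # (-lo, -lo)
    b = padded[0:h, window - 1:w + window - 1]    # (-lo, +hi)
    c = padded[window - 1:h + window - 1, window - 1:w + window - 1]  # (+hi, +hi)
    e = padded[window - 1:h + window - 1, 0:w]    # (+hi, -lo)
    center = (a + b + c + e) / 4.0
    half = d / 2.0

    def tri_area(z1, z2, zc):
        # triangle between an edge of the cell and the center: corner1 at
        # (0,0,z1), corner2 at (d,0,z2), center at (d/2,d/2,zc) — by symmetry
        # the same formula serves all four edges; area = |v1 x v2| / 2
        v1z = z2 - z1
        v2z = zc - z1
        cross_x = -v1z * half
        cross_y = v1z * half - d * v2z
        cross_z = d * half
        return 0.5 * np.sqrt(cross_x**2 + cross_y**2 + cross_z**2)

    area = tri_area(a, b, center) + tri_area(b, c, center) + tri_area(c, e, center) + tri_area(e, a, center)
    return area / (d * d)


def local_fractal_dimension(image: ImageGrid, cfg: FilterConfig | None = None) -> ImageGrid:
    """Local fractal dimension via the triangular prism method at three scales.

    D = 2 - slope of log(normalized prism area) vs log(scale), least-squares
    over the three scales, clipped to [2, 3].  Flat and affine surfaces give
    D = 2; rough, scale-repeating texture pushes D toward 3.
    """
    cfg = cfg or FilterConfig()
    scales = cfg.lfd_scales
    logs = np.log([s - 1 for s in scales])
    logs_c = logs - logs.mean()
    denom = float((logs_c**2).sum())
    num = np.zeros_like(image.pixels, dtype=np.float64)
    log_areas = []
    for s in scales:
        area = np.maximum(_prism_surface_area(image.pixels, s), 1e-300)
        log_areas.append(np.log(area))
    mean_la = sum(log_areas) / 3.0
    for la, lc in zip(log_areas, logs_c):
        num += (la - mean_la) * lc
    slope = num / denom
    return image.with_pixels(np.clip(2.0 - slope, 2.0, 3.0))
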