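"""The 43-feature bank, per-view image stacks, and per-subject vectors.

Each image contributes 43 first-order features in three groups:

* shape (f01-f08): computed on the tissue mask alone — area, compactness
  P^2/A (the perimeter P counts exposed 4-neighbor pixel edges), elongation
  of the bounding box, binary centroid, and the three second-order central
  moments ("region scatter");
* signal (f09-f36): histogram statistics of the masked intensities — mean,
  median, energy, variance, SD, dynamic range, z-mean, entropy, skewness,
  excess kurtosis, z-range, four tail fractions beyond 2 and 3 SD, ten
  quantiles, and 5%-trimmed mean/SD/z-mean;
* morphology (f37-f43): intensity-weighted moments — total signal mass,
  signal centroid, signal scatter, and the signal surface area.

Histogram features index integer intensity bins: raw and MoF images are
already integer-valued and are binned at unit width; signed or fractional
maps (LoG, LSD, LFD, subtraction-derived floats) are linearly quantized to
1,024 bins over their masked min-max range first, and the statistics are
computed on the bin indices.

A subject's vector holds 43 features for each of 15 images per view
(I, H=MoF, L=LoG, S=LSD, F=LFD, each for the right, left, and subtraction
image) across both views (1,290 values) plus, for every view/variant pair,
the left-right average and absolute difference of each feature
(860 symmetric values): 2,150 named entries in total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filters import FilterConfig, local_fractal_dimension, local_std, log_filter, mof
from .grids import ImageGrid
from .registration import bilateral_subtract

VARIANTS = ("I", "H", "L", "S", "F")  # raw, MoF, LoG, LSD, LFD
STACK_SIDES = ("r", "l", "d")  # right, left, bilateral subtraction
SYMMETRIC_KINDS = ("avg", "absdiff")
N_FEATURES_PER_IMAGE = 43
HISTOGRAM_BINS_FLOAT = 1024

SHAPE_NAMES = (
    "area",
    "compactness",
    "elongation",
    "centroid_x",
    "centroid_y",
    "scatter_xx",
    "scatter_xy",
    "scatter_yy",
)


class EmptyMaskError(ValueError):
    """Raised when a feature is requested for an empty mask."""


# ---------------------------------------------------------------------------
# shape features (mask only)
# ---------------------------------------------------------------------------

def mask_perimeter(mask: np.ndarray) -> int:
    """Perimeter as the count of exposed 4-neighbor pixel edges."""
    m = np.asarray(mask, bool)
    p = np.pad(m, 1, constant_values=False)
    exposed = 0
    for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neighbor = np.roll(p, shift, axis=(0, 1))
        exposed += int(np.count_nonzero(p & ~neighbor))
    return exposed


def shape_features(mask: np.ndarray) -> dict[str, float]:
    """The eight shape features of the bank (perimeter feeds compactness only)."""
    m = np.asarray(mask, bool)
    ys, xs = np.nonzero(m)
    if xs.size == 0:
        raise EmptyMaskError("shape features require a non-empty mask")
    area = float(xs.size)
    perimeter = float(mask_perimeter(m))
    lx = float(xs.max() - xs.min() + 1)
    ly = float(ys.max() - ys.min() + 1)
    x = xs.astype(np.float64)
    y = ys.astype(np.float64)
    cx = x.mean()
    cy = y.mean()
    return {
        "area": area,
        "compactness": perimeter**2 / area,
        "elongation": max(lx, ly) / min(lx, ly),
        "centroid_x": cx,
        "centroid_y": cy,
        "scatter_xx": float((x**2).mean() - cx**2),
        "scatter_xy": float((x * y).mean() - cx * cy),
        "scatter_yy": float((y**2).mean() - cy**2),
    }


# ---------------------------------------------------------------------------
# signal features (histogram over integer bins)
# ---------------------------------------------------------------------------

QUANTILE_PS = (0.0001, 0.001, 0.01, 0.05, 0.25, 0.75, 0.95, 0.99, 0.999, 0.9999)


def quantize_masked_values(image: ImageGrid, binning: str) -> np.ndarray:
    """Integer values entering the histogram features.

    ``binning="integer"``: round to the native integer intensities (raw and
    MoF images).  ``binning="minmax1024"``: linear quantization of the
    masked min-max range onto bin indices 0..1023 (float-valued maps).
    """
    values = image.masked_values()
    if values.size == 0:
        raise EmptyMaskError("signal features require a non-empty mask")
    if binning == "integer":
        return np.round(values).astype(np.int64)
    if binning == "minmax1024":
        lo = values.min()
        span = values.max() - lo
        if span == 0:
            return np.zeros(values.size, dtype=np.int64)
        return np.round((values - lo) / span * (HISTOGRAM_BINS_FLOAT - 1)).astype(np.int64)
    raise ValueError(f"unknown binning {binning!r}")


def _quantile_sorted(sorted_values: np.ndarray, p: float) -> float:
    """Linear-interpolation quantile v(p) of the empirical distribution."""
    n = sorted_values.size
    h = (n - 1) * p
    k = int(np.floor(h))
    if k + 1 >= n:
        return float(sorted_values[-1])
    return float(sorted_values[k] + (h - k) * (sorted_values[k + 1] - sorted_values[k]))


def signal_features(values: np.ndarray) -> dict[str, float]:
    """The 28 histogram features from integer-binned masked values."""
    v = np.asarray(values, dtype=np.int64)
    if v.size == 0:
        raise EmptyMaskError("signal features require a non-empty mask")
    if v.min() < 0:
        raise ValueError("binned values must be non-negative")
    n = v.size
    counts = np.bincount(v)
    i = np.arange(counts.size, dtype=np.float64)
    f = counts / n
    mean = float((i * f).sum())
    energy = float((i**2 * f).sum())
    var = max(energy - mean**2, 0.0)
    sd = float(np.sqrt(var))
    vmin, vmax = float(v.min()), float(v.max())
    drange = vmax - vmin
    nz = f > 0
    entropy = float(-(f[nz] * np.log(f[nz])).sum())
    sorted_v = np.sort(v)

    def cdf(t: float) -> float:
        return float(np.searchsorted(sorted_v, t, side="right")) / n

    if sd > 0:
        z = (i - mean) / sd
        skew = float((z**3 * f).sum())
        kurt = float((z**4 * f).sum() - 3.0)
        zmean = mean / sd
        zrange = drange / sd
    else:
        skew = kurt = zmean = zrange = 0.0
    tails_hi = [1.0 - cdf(mean + zz * sd) for zz in (2.0, 3.0)]
    tails_lo = [cdf(mean - zz * sd) for zz in (2.0, 3.0)]
    quantiles = [_quantile_sorted(sorted_v, p) for p in QUANTILE_PS]

    lo, hi = _quantile_sorted(sorted_v, 0.05), _quantile_sorted(sorted_v, 0.95)
    sel = nz & (i >= lo) & (i <= hi)
    if sel.any():
        ft = f[sel] / f[sel].sum()
        it = i[sel]
        tmean = float((it * ft).sum())
        tvar = max(float((it**2 * ft).sum()) - tmean**2, 0.0)
        tsd = float(np.sqrt(tvar))
    else:  # degenerate: trimming removed everything, fall back to all bins
        tmean, tsd = mean, sd
    tzmean = tmean / tsd if tsd > 0 else 0.0

    out = {
        "mean": mean,
        "median": _quantile_sorted(sorted_v, 0.5),
        "energy": energy,
        "variance": var,
        "std": sd,
        "dynamic_range": drange,
        "z_mean": zmean,
        "entropy": entropy,
        "skewness": skew,
        "kurtosis": kurt,
        "z_range": zrange,
        "frac_above_2sd": tails_hi[0],
        "frac_above_3sd": tails_hi[1],
        "frac_below_2sd": tails_lo[0],
        "frac_below_3sd": tails_lo[1],
    }
    for p, q in zip(QUANTILE_PS, quantiles):
        out[f"quantile_{p:g}"] = q
    out["trimmed_mean"] = tmean
    out["trimmed_std"] = tsd
    out["trimmed_z_mean"] = tzmean
    return out


# ---------------------------------------------------------------------------
# morphology features (intensity-weighted moments)
# ---------------------------------------------------------------------------

def _neighbor_mean(pixels: np.ndarray) -> np.ndarray:
    """Mean of the 4-neighbors with replicate edge handling."""
    p = np.pad(pixels, 1, mode="edge")
    return (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:]) / 4.0


def morphology_features(image: ImageGrid, pixel_spacing: float = 1.0) -> dict[str, float]:
    """Signal mass, centroid, scatter and surface area over the mask."""
    mask = image.mask if image.mask is not None else np.ones(image.shape, bool)
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise EmptyMaskError("morphology features require a non-empty mask")
    vals = image.pixels[ys, xs]
    x = xs.astype(np.float64)
    y = ys.astype(np.float64)
    m00 = float(vals.sum())
    if m00 != 0.0:
        cx = float((x * vals).sum()) / m00
        cy = float((y * vals).sum()) / m00
        sxx = float((x**2 * vals).sum()) / m00 - cx**2
        sxy = float((x * y * vals).sum()) / m00 - cx * cy
        syy = float((y**2 * vals).sum()) / m00 - cy**2
    else:  # zero total mass: centroid undefined, report zeros
        cx = cy = sxx = sxy = syy = 0.0
    dxy = pixel_spacing
    diff = image.pixels[ys, xs] - _neighbor_mean(image.pixels)[ys, xs]
    surface = float(dxy * np.sqrt(dxy**2 + 4.0 * diff**2).sum() / 2.0)
    return {
        "signal_mass": m00,
        "signal_centroid_x": cx,
        "signal_centroid_y": cy,
        "signal_scatter_xx": sxx,
        "signal_scatter_xy": sxy,
        "signal_scatter_yy": syy,
        "signal_surface": surface,
    }


# ---------------------------------------------------------------------------
# per-image and per-subject assembly
# ---------------------------------------------------------------------------

SIGNAL_NAMES = (
    "mean", "median", "energy", "variance", "std", "dynamic_range", "z_mean",
    "entropy", "skewness", "kurtosis", "z_range",
    "frac_above_2sd", "frac_above_3sd", "frac_below_2sd", "frac_below_3sd",
    *[f"quantile_{p:g}" for p in QUANTILE_PS],
    "trimmed_mean", "trimmed_std", "trimmed_z_mean",
)
MORPHOLOGY_NAMES = (
    "signal_mass", "signal_centroid_x", "signal_centroid_y",
    "signal_scatter_xx", "signal_scatter_xy", "signal_scatter_yy",
    "signal_surface",
)
FEATURE_NAMES: tuple[str, ...] = SHAPE_NAMES + SIGNAL_NAMES + MORPHOLOGY_NAMES
assert len(FEATURE_NAMES) == N_FEATURES_PER_IMAGE


def extract_image_features(image: ImageGrid, binning: str = "integer") -> dict[str, float]:
    """All 43 features of one masked image, keyed f01..f43."""
    if image.mask is None:
        raise ValueError("extract_image_features requires an image with a mask")
    values = quantize_masked_values(image, binning)
    feats: dict[str, float] = {}
    feats.update(shape_features(image.mask))
    feats.update(signal_features(values))
    feats.update(morphology_features(image))
    return {f"f{k + 1:02d}": float(feats[name]) for k, name in enumerate(FEATURE_NAMES)}


@dataclass
class BilateralViewStack:
    """The 15 per-view images: 5 variants x (right, left, subtraction)."""

    view: str
    images: dict[tuple[str, str], ImageGrid]  # (variant, side) -> image

    def __post_init__(self) -> None:
        expected = {(v, s) for v in VARIANTS for s in STACK_SIDES}
        if set(self.images) != expected:
            raise ValueError("a view stack requires exactly 15 images")


def build_view_stack(
    view: str,
    right: ImageGrid,
    left: ImageGrid,
    warped_left: ImageGrid,
    cfg: FilterConfig | None = None,
) -> BilateralViewStack:
    """Subtract, then apply the four operators to right, left and subtraction.

    ``right`` and ``left`` are the segmented (masked, background-zeroed)
    raw views in their native orientations; ``warped_left`` is the mirrored
    left image registered into right-image space, used only to form the
    subtraction map.
    """
    cfg = cfg or FilterConfig()
    delta = bilateral_subtract(right, warped_left)
    bases = {"r": right, "l": left, "d": delta}
    ops = {"H": mof, "L": log_filter, "S": local_std, "F": local_fractal_dimension}
    images: dict[tuple[str, str], ImageGrid] = {}
    for side, base in bases.items():
        images[("I", side)] = base
        for code, op in ops.items():
            images[(code, side)] = op(base, cfg)
    return BilateralViewStack(view=view, images=images)


def _binning_for(variant: str, side: str) -> str:
    # raw and MoF keep native integer intensities except on the fractional
    # subtraction-derived maps; LoG/LSD/LFD are always float-valued
    if variant in ("I", "H") and side != "d":
        return "integer"
    if variant in ("I", "H"):
        # subtraction maps are |int - interpolated float|: fractional
        return "minmax1024"
    return "minmax1024"


def build_subject_vector(cc: BilateralViewStack, mlo: BilateralViewStack) -> pd.Series:
    """The named 2,150-entry per-subject feature vector.

    Naming: ``{VIEW}_{VARIANT}_{SIDE}_f{NN}`` for the 1,290 per-image
    features and ``{VIEW}_{VARIANT}_{avg|absdiff}_f{NN}`` for the 860
    symmetric features; entries are ordered lexicographically.
    """
    stacks = {"CC": cc, "MLO": mlo}
    values: dict[str, float] = {}
    for view, stack in stacks.items():
        if stack.view != view:
            raise ValueError(f"stack labelled {stack.view!r} passed as {view}")
        for variant in VARIANTS:
            per_side: dict[str, dict[str, float]] = {}
            for side in STACK_SIDES:
                feats = extract_image_features(
                    stack.images[(variant, side)], _binning_for(variant, side)
                )
                per_side[side] = feats
                for key, val in feats.items():
                    values[f"{view}_{variant}_{side}_{key}"] = val
            for key in per_side["r"]:
                r, l = per_side["r"][key], per_side["l"][key]
                values[f"{view}_{variant}_avg_{key}"] = (r + l) / 2.0
                values[f"{view}_{variant}_absdiff_{key}"] = abs(r - l)
    series = pd.Series(values, dtype=np.float64).sort_index()
    n_expected = N_FEATURES_PER_IMAGE * (15 * 2 + 2 * 5 * 2)
    if series.size != n_expected:
        raise AssertionError(f"feature vector has {series.size} entries, expected {n_expected}")
    return series
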