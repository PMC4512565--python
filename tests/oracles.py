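"""Independent brute-force oracles for filters and the feature bank.

Everything here is written as naive per-pixel double loops straight from
the defining formulas, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def _pad_replicate(img: np.ndarray, lo: int, hi: int) -> np.ndarray:
    return np.pad(img, ((lo, hi), (lo, hi)), mode="edge")


def mof_loops(img: np.ndarray, size: int = 5) -> np.ndarray:
    lo = size // 2
    p = _pad_replicate(img.astype(float), lo, lo)
    out = np.empty_like(img, dtype=float)
    h, w = img.shape
    for y in range(h):
        for x in range(w):
            out[y, x] = img[y, x] - p[y : y + size, x : x + size].min()
    return out


def laplacian_loops(img: np.ndarray) -> np.ndarray:
    """3x3 discrete Laplacian with replicate padding (applied after smoothing)."""
    p = _pad_replicate(img.astype(float), 1, 1)
    out = np.empty_like(img, dtype=float)
    h, w = img.shape
    for y in range(h):
        for x in range(w):
            out[y, x] = (
                p[y, x + 1] + p[y + 2, x + 1] + p[y + 1, x] + p[y + 1, x + 2]
                - 4 * p[y + 1, x + 1]
            )
    return out


def local_std_loops(img: np.ndarray, size: int = 3) -> np.ndarray:
    lo = size // 2
    p = _pad_replicate(img.astype(float), lo, lo)
    out = np.empty_like(img, dtype=float)
    h, w = img.shape
    n = size * size
    for y in range(h):
        for x in range(w):
            win = p[y : y + size, x : x + size]
            m2 = (win**2).sum() / n
            m1 = win.sum() / n
            out[y, x] = math.sqrt(max(m2 - m1 * m1, 0.0))
    return out


def _tri_area_3d(p1, p2, p3) -> float:
    v1 = np.subtract(p2, p1)
    v2 = np.subtract(p3, p1)
    return 0.5 * float(np.linalg.norm(np.cross(v1, v2)))


def prism_area_loops(img: np.ndarray, window: int) -> np.ndarray:
    """Normalized triangular-prism surface area per pixel at one window size."""
    lo = (window - 1) // 2
    hi = window - 1 - lo
    d = float(window - 1)
    p = _pad_replicate(img.astype(float), lo, hi)
    h, w = img.shape
    out = np.empty((h, w), dtype=float)
    for y in range(h):
        for x in range(w):
            a = p[y, x]
            b = p[y, x + window - 1]
            c = p[y + window - 1, x + window - 1]
            e = p[y + window - 1, x]
            zc = (a + b + c + e) / 4.0
            pa = (0.0, 0.0, a)
            pb = (d, 0.0, b)
            pc = (d, d, c)
            pe = (0.0, d, e)
            ctr = (d / 2, d / 2, zc)
            area = (
                _tri_area_3d(pa, pb, ctr)
                + _tri_area_3d(pb, pc, ctr)
                + _tri_area_3d(pc, pe, ctr)
                + _tri_area_3d(pe, pa, ctr)
            )
            out[y, x] = area / (d * d)
    return out


def lfd_loops(img: np.ndarray, scales=(3, 5, 9)) -> np.ndarray:
    logs = [math.log(s - 1) for s in scales]
    areas = [prism_area_loops(img, s) for s in scales]
    h, w = img.shape
    out = np.empty((h, w), dtype=float)
    mlog = sum(logs) / len(logs)
    den = sum((lg - mlog) ** 2 for lg in logs)
    for y in range(h):
        for x in range(w):
            la = [math.log(max(a[y, x], 1e-300)) for a in areas]
            mla = sum(la) / len(la)
            slope = sum((lg - mlog) * (v - mla) for lg, v in zip(logs, la)) / den
            out[y, x] = min(max(2.0 - slope, 2.0), 3.0)
    return out


# ---------------------------------------------------------------------------
# feature-bank oracles
# ---------------------------------------------------------------------------

def shape_loops(mask: np.ndarray) -> list[float]:
    h, w = mask.shape
    area = perim = 0
    xs, ys = [], []
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            area += 1
            xs.append(x)
            ys.append(y)
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ny, nx = y + dy, x + dx
                if not (0 <= ny < h and 0 <= nx < w) or not mask[ny, nx]:
                    perim += 1
    lx = max(xs) - min(xs) + 1
    ly = max(ys) - min(ys) + 1
    m = {}
    for p in range(3):
        for q in range(3):
            m[(p, q)] = sum(x**p * y**q for x, y in zip(xs, ys))
    cx = m[(1, 0)] / m[(0, 0)]
    cy = m[(0, 1)] / m[(0, 0)]
    return [
        float(area),
        perim**2 / area,
        max(lx, ly) / min(lx, ly),
        cx,
        cy,
        m[(2, 0)] / m[(0, 0)] - cx * cx,
        m[(1, 1)] / m[(0, 0)] - cx * cy,
        m[(0, 2)] / m[(0, 0)] - cy * cy,
    ]


def _quantile_loops(values: list[float], p: float) -> float:
    s = sorted(values)
    h = (len(s) - 1) * p
    k = int(math.floor(h))
    if k + 1 >= len(s):
        return float(s[-1])
    return s[k] + (h - k) * (s[k + 1] - s[k])


def signal_loops(values: list[int]) -> list[float]:
    """The 28 histogram features straight from the raw value list."""
    n = len(values)
    mean = sum(values) / n
    energy = sum(v * v for v in values) / n
    var = max(energy - mean * mean, 0.0)
    sd = math.sqrt(var)
    vmin, vmax = min(values), max(values)
    dr = float(vmax - vmin)
    from collections import Counter

    counts = Counter(values)
    entropy = -sum((c / n) * math.log(c / n) for c in counts.values())
    if sd > 0:
        skew = sum(((v - mean) / sd) ** 3 for v in values) / n
        kurt = sum(((v - mean) / sd) ** 4 for v in values) / n - 3.0
        zmean = mean / sd
        zrange = dr / sd
    else:
        skew = kurt = zmean = zrange = 0.0
    frac_above = lambda t: sum(v > t for v in values) / n
    frac_below_eq = lambda t: sum(v <= t for v in values) / n
    tails = [
        frac_above(mean + 2 * sd),
        frac_above(mean + 3 * sd),
        frac_below_eq(mean - 2 * sd),
        frac_below_eq(mean - 3 * sd),
    ]
    ps = (0.0001, 0.001, 0.01, 0.05, 0.25, 0.75, 0.95, 0.99, 0.999, 0.9999)
    quants = [_quantile_loops(values, p) for p in ps]
    lo = _quantile_loops(values, 0.05)
    hi = _quantile_loops(values, 0.95)
    trimmed = [v for v in values if lo <= v <= hi]
    if trimmed:
        tmean = sum(trimmed) / len(trimmed)
        tvar = max(sum(v * v for v in trimmed) / len(trimmed) - tmean * tmean, 0.0)
        tsd = math.sqrt(tvar)
    else:
        tmean, tsd = mean, sd
    tz = tmean / tsd if tsd > 0 else 0.0
    return (
        [mean, _quantile_loops(values, 0.5), energy, var, sd, dr, zmean, entropy, skew, kurt, zrange]
        + tails
        + quants
        + [tmean, tsd, tz]
    )


def morphology_loops(img: np.ndarray, mask: np.ndarray) -> list[float]:
    h, w = img.shape
    m = {}
    for p in range(3):
        for q in range(3):
            m[(p, q)] = sum(
                (x**p) * (y**q) * img[y, x] for y in range(h) for x in range(w) if mask[y, x]
            )
    m00 = m[(0, 0)]
    if m00 != 0:
        cx = m[(1, 0)] / m00
        cy = m[(0, 1)] / m00
        sxx = m[(2, 0)] / m00 - cx * cx
        sxy = m[(1, 1)] / m00 - cx * cy
        syy = m[(0, 2)] / m00 - cy * cy
    else:
        cx = cy = sxx = sxy = syy = 0.0
    pad = _pad_replicate(img.astype(float), 1, 1)
    surface = 0.0
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            nb = (pad[y, x + 1] + pad[y + 2, x + 1] + pad[y + 1, x] + pad[y + 1, x + 2]) / 4.0
            surface += math.sqrt(1.0 + 4.0 * (img[y, x] - nb) ** 2)
    return [m00, cx, cy, sxx, sxy, syy, surface / 2.0]


def all_features_loops(img: np.ndarray, mask: np.ndarray) -> list[float]:
    """All 43 features of an integer-valued masked patch, in bank order."""
    values = [int(round(img[y, x])) for y in range(img.shape[0]) for x in range(img.shape[1]) if mask[y, x]]
    return shape_loops(mask) + signal_loops(values) + morphology_loops(img, mask)


def auc_pairs(scores, labels) -> float:
    """AUC by direct enumeration of positive-negative pairs (ties = 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))
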