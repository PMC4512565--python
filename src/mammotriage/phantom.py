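"""Synthetic mammogram phantoms with controllable left-right asymmetry.

Real screening sets consist of four films per subject (right/left CC and
MLO projections, 12-bit film digitizations).  The phantom emulates the
aspects of those data that the pipeline actually exploits:

* a single smooth breast-shaped tissue region anchored to the chest-wall
  edge of the frame (left edge for right-breast images, right edge for
  left-breast images), bright against a noisy dark background — what the
  noise-threshold segmentation needs;
* smooth low-frequency internal texture shared between the two sides, so
  that a healthy subject is nearly bilaterally symmetric;
* a smooth random deformation between the two sides, emulating positioning
  and compression differences — what the deformable registration corrects;
* optional unilateral lesions: a single low-frequency Gaussian blob
  ("mass") or a cluster of 1–2 px high-intensity points ("calcification"),
  the high- vs low-frequency distinction the enhancement filters target.

It does not attempt photorealism, X-ray physics, or film digitization
artifacts; see the methods note for what that implies about the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .grids import ImageGrid, write_image

VIEWS = ("CC", "MLO")
SIDES = ("r", "l")
LABELS = ("HS", "CS", "MS")  # healthy / malignant calcifications / malignant masses


@dataclass
class PhantomParams:
    """Generation parameters for one synthetic subject.

    Intensities are in raw detector units on a ``bit_depth``-bit scale;
    lengths are in pixels.
    """

    image_height: int = 256
    image_width: int = 192
    bit_depth: int = 12
    background_level: float = 50.0  # film-base pedestal the noise rides on
    background_noise_sd: float = 5.0
    tissue_base_intensity: float = 600.0
    lesion_kind: str = "none"  # none | mass | calcification
    lesion_side: str = "left"  # left | right
    lesion_contrast: float = 400.0
    lesion_count: int = 12
    deformation_amplitude: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 8 <= self.bit_depth <= 16:
            raise ValueError("bit_depth must be in [8, 16]")
        if self.lesion_kind not in ("none", "mass", "calcification"):
            raise ValueError(f"unknown lesion_kind {self.lesion_kind!r}")
        if self.lesion_side not in ("left", "right"):
            raise ValueError(f"unknown lesion_side {self.lesion_side!r}")
        if self.lesion_contrast < 0:
            raise ValueError("lesion_contrast must be non-negative")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be non-negative")
        if self.image_height < 32 or self.image_width < 32:
            raise ValueError("phantom images must be at least 32x32")


@dataclass
class MammogramSet:
    """One subject's four standard views plus optional ground truth.

    ``images`` maps ``(view, side)`` with view in {"CC", "MLO"} and side in
    {"r", "l"}.  ``truth`` carries the generator's tissue and lesion masks
    (in each image's own orientation) for validation; real data has none.
    """

    subject_id: str
    label: str
    images: dict[tuple[str, str], ImageGrid]
    truth: dict[str, dict[tuple[str, str], np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        expected = {(v, s) for v in VIEWS for s in SIDES}
        if set(self.images) != expected:
            raise ValueError("a mammogram set requires exactly the four standard views")


def _breast_geometry(h: int, w: int, view: str, rng: np.random.Generator):
    """Normalized elliptical radius u and angle for a right-breast frame.

    The tissue occupies u <= rho(theta): a half-ellipse anchored to the left
    (chest-wall) edge with a smooth low-order harmonic boundary perturbation.
    """
    a = (0.80 if view == "CC" else 0.74) * w
    b = (0.42 if view == "CC" else 0.47) * h
    cy = (h - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    ex = xx / a
    ey = (yy - cy) / b
    u = np.hypot(ex, ey)
    theta = np.arctan2(ey, ex)
    amp = rng.uniform(0.015, 0.035, size=3)
    phase = rng.uniform(0, 2 * np.pi, size=3)
    rho = 1.0 + sum(amp[k] * np.cos((k + 2) * theta + phase[k]) for k in range(3))
    return u / rho, a, b, cy


def _tissue_image(params: PhantomParams, view: str, rng: np.random.Generator):
    """Canonical (right-geometry) noiseless tissue image and its mask."""
    h, w = params.image_height, params.image_width
    u, a, b, cy = _breast_geometry(h, w, view, rng)
    inside = u <= 1.0
    base = params.tissue_base_intensity
    profile = np.where(inside, base * (0.35 + 0.65 * np.cos(np.minimum(u, 1.0) * np.pi / 2)), 0.0)
    # two texture scales: coarse parenchymal density + finer structural detail
    coarse = gaussian_filter(rng.standard_normal((h, w)), sigma=8.0)
    fine = gaussian_filter(rng.standard_normal((h, w)), sigma=2.0)
    for t in (coarse, fine):
        sd = t.std()
        if sd > 0:
            t /= sd
    tissue = profile + inside * base * (0.08 * coarse + 0.04 * fine)
    return np.clip(tissue, 0.0, None), inside, (a, b, cy)


def _insert_lesion(tissue: np.ndarray, params: PhantomParams, geom, rng: np.random.Generator):
    """Add a mass blob or calcification cluster; returns (image, footprint)."""
    h, w = tissue.shape
    a, b, cy = geom
    # interior anchor, jittered, kept well inside the tissue blob
    cx0 = 0.45 * a + rng.uniform(-0.05, 0.05) * a
    cy0 = cy + rng.uniform(-0.2, 0.2) * b
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    footprint = np.zeros((h, w), dtype=bool)
    out = tissue.copy()
    if params.lesion_kind == "mass":
        sd = rng.uniform(10.0, 20.0)
        r2 = (xx - cx0) ** 2 + (yy - cy0) ** 2
        blob = params.lesion_contrast * np.exp(-r2 / (2 * sd * sd))
        out += blob
        footprint = r2 <= (2 * sd) ** 2
    elif params.lesion_kind == "calcification":
        for _ in range(max(params.lesion_count, 0)):
            ang = rng.uniform(0, 2 * np.pi)
            rad = 15.0 * np.sqrt(rng.uniform())
            px = cx0 + rad * np.cos(ang)
            py = cy0 + rad * np.sin(ang)
            pr = rng.uniform(1.0, 2.0)
            spot = (xx - px) ** 2 + (yy - py) ** 2 <= pr * pr
            out += params.lesion_contrast * spot
            footprint |= spot
    return out, footprint


def _smooth_warp(image: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Resample through a smooth random displacement field of max |d| = amplitude."""
    if amplitude == 0:
        return image
    h, w = image.shape
    disp = gaussian_filter(rng.standard_normal((2, h, w)), sigma=(0, h / 6, w / 6))
    peak = np.abs(disp).max()
    if peak > 0:
        disp *= amplitude / peak
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    return map_coordinates(image, [yy + disp[0], xx + disp[1]], order=1, mode="nearest")


def generate_subject(params: PhantomParams, subject_id: str = "S000", label: str | None = None) -> MammogramSet:
    """Generate one subject's four views deterministically from ``params.seed``.

    The two sides of a view share the same tissue field; the left side is a
    smoothly deformed, mirrored copy, so with zero deformation, zero noise
    and no lesion the left image equals the mirrored right image exactly.
    """
    if label is None:
        label = {"none": "HS", "calcification": "CS", "mass": "MS"}[params.lesion_kind]
    rng = np.random.default_rng(params.seed)
    maxval = 2**params.bit_depth - 1
    images: dict[tuple[str, str], ImageGrid] = {}
    tissue_truth: dict[tuple[str, str], np.ndarray] = {}
    lesion_truth: dict[tuple[str, str], np.ndarray] = {}
    for view in VIEWS:
        tissue, inside, geom = _tissue_image(params, view, rng)
        sides: dict[str, np.ndarray] = {}
        feet: dict[str, np.ndarray] = {}
        for side in SIDES:
            img = tissue
            foot = np.zeros_like(inside)
            wants_lesion = params.lesion_kind != "none" and (
                (side == "r") == (params.lesion_side == "right")
            )
            if wants_lesion:
                img, foot = _insert_lesion(img, params, geom, rng)
            elif params.lesion_kind != "none":
                # burn the identical draws so both sides see the same stream
                _insert_lesion(img, params, geom, np.random.default_rng(rng.integers(2**31)))
            if side == "l":
                img = _smooth_warp(img, params.deformation_amplitude, rng)
                img = img[:, ::-1]
                foot = foot[:, ::-1]
            sides[side] = img
            feet[side] = foot
        for side in SIDES:
            noisy = sides[side] + params.background_level + (
                rng.normal(0.0, params.background_noise_sd, sides[side].shape)
                if params.background_noise_sd > 0
                else 0.0
            )
            arr = np.clip(np.round(noisy), 0, maxval)
            images[(view, side)] = ImageGrid(arr, bit_depth=params.bit_depth)
            tissue_truth[(view, side)] = sides[side] > 0
            lesion_truth[(view, side)] = feet[side]
    return MammogramSet(
        subject_id=subject_id,
        label=label,
        images=images,
        truth={"tissue": tissue_truth, "lesion": lesion_truth},
    )


def _subject_seed(cohort_seed: int, index: int) -> int:
    """Deterministic per-subject seed derived from the cohort seed."""
    return int(np.random.SeedSequence([cohort_seed, index]).generate_state(1)[0] % 2**31)


def generate_cohort(
    n_hs: int,
    n_cs: int,
    n_ms: int,
    base_params: PhantomParams | None = None,
    seed: int = 0,
) -> list[MammogramSet]:
    """Generate a labelled cohort; lesion side drawn uniformly per diseased subject."""
    if min(n_hs, n_cs, n_ms) < 0:
        raise ValueError("cohort counts must be non-negative")
    if base_params is None:
        base_params = PhantomParams()
    labels = ["HS"] * n_hs + ["CS"] * n_cs + ["MS"] * n_ms
    kinds = {"HS": "none", "CS": "calcification", "MS": "mass"}
    subjects = []
    for i, label in enumerate(labels):
        sseed = _subject_seed(seed, i)
        side_rng = np.random.default_rng(_subject_seed(seed, 10**6 + i))
        side = "left" if side_rng.uniform() < 0.5 else "right"
        p = replace(base_params, lesion_kind=kinds[label], lesion_side=side, seed=sseed)
        subjects.append(generate_subject(p, subject_id=f"{label}{i:04d}", label=label))
    return subjects


def write_cohort(subjects: list[MammogramSet], out_dir: str | Path, fmt: str = "tif") -> Path:
    """Write each subject's four images plus a manifest CSV; returns manifest path."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        row: dict[str, str] = {"subject_id": s.subject_id, "label": s.label}
        for view in VIEWS:
            for side in SIDES:
                name = f"{s.subject_id}_{view.lower()}_{side}.{fmt}"
                write_image(s.images[(view, side)], out_dir / name)
                row[f"path_{view.lower()}_{side}"] = name
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    columns = ["subject_id", "label", "path_cc_r", "path_cc_l", "path_mlo_r", "path_mlo_l"]
    pd.DataFrame(rows, columns=columns).to_csv(manifest, index=False)
    return manifest
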