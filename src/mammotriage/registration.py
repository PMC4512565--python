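"""Bilateral registration and subtraction.

Left views are mirrored and deformably registered onto the corresponding
right views with a multiresolution B-spline transform driven by the Mattes
mutual information metric (coarse-to-fine, parameters propagated between
levels).  The bilateral subtraction map is the pixelwise absolute
difference between the right image and the warped left image; asymmetric
structure — a unilateral lesion, architectural distortion — survives the
subtraction while symmetric anatomy cancels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from .grids import ImageGrid


@dataclass
class RegistrationConfig:
    """B-spline registration knobs (pixels unless noted)."""

    n_resolutions: int = 3
    grid_spacing_finest: float = 64.0
    mi_bins: int = 50
    max_iterations_per_level: int = 200
    sampling_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resolutions < 1:
            raise ValueError("n_resolutions must be >= 1")
        if self.mi_bins < 8:
            raise ValueError("mi_bins must be >= 8")
        if not 0 < self.sampling_fraction <= 1:
            raise ValueError("sampling_fraction must be in (0, 1]")


@dataclass
class RegistrationResult:
    """Transform, warped moving image, and metric bookkeeping.

    The metric is Mattes mutual information under ITK's minimized sign
    convention (more negative is better); ``metric_final`` never exceeds
    ``metric_initial`` — if optimization cannot beat the identity, the
    identity transform is kept.  ``converged`` is False when the optimizer
    failed or the transform folds (non-positive Jacobian determinant
    anywhere); such subjects are excluded from cohort analyses.
    """

    transform: sitk.Transform
    warped_moving: ImageGrid
    metric_initial: float
    metric_final: float
    converged: bool
    displacement: np.ndarray  # (2, H, W): dy, dx per fixed-image pixel


def mirror_horizontal(image: ImageGrid) -> ImageGrid:
    """Reverse columns; the mask is mirrored identically."""
    mask = None if image.mask is None else image.mask[:, ::-1].copy()
    return ImageGrid(image.pixels[:, ::-1].copy(), image.bit_depth, mask)


def _to_sitk(image: ImageGrid) -> sitk.Image:
    return sitk.GetImageFromArray(image.pixels.astype(np.float32))


def _displacement_field(transform: sitk.Transform, reference: sitk.Image) -> np.ndarray:
    field = sitk.TransformToDisplacementField(
        transform,
        sitk.sitkVectorFloat64,
        reference.GetSize(),
        reference.GetOrigin(),
        reference.GetSpacing(),
        reference.GetDirection(),
    )
    arr = sitk.GetArrayFromImage(field)  # (H, W, 2) as (dx, dy)
    return np.stack([arr[..., 1], arr[..., 0]])


def _jacobian_min(transform: sitk.Transform, reference: sitk.Image) -> float:
    field = sitk.TransformToDisplacementField(
        transform,
        sitk.sitkVectorFloat64,
        reference.GetSize(),
        reference.GetOrigin(),
        reference.GetSpacing(),
        reference.GetDirection(),
    )
    jac = sitk.DisplacementFieldJacobianDeterminant(field)
    return float(sitk.GetArrayFromImage(jac).min())


def _sampling_seed(config: RegistrationConfig) -> int:
    # seed 0 means "wall clock" to ITK; keep the derived seed nonzero
    return (config.seed % (2**31 - 2)) + 1


def _metric_value(fixed: sitk.Image, moving: sitk.Image, transform: sitk.Transform, config: RegistrationConfig) -> float:
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=config.mi_bins)
    reg.SetMetricSamplingStrategy(reg.RANDOM)
    reg.SetMetricSamplingPercentage(config.sampling_fraction, _sampling_seed(config))
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetInitialTransform(transform, inPlace=False)
    return float(reg.MetricEvaluate(fixed, moving))


def register_bspline(
    fixed: ImageGrid, moving: ImageGrid, config: RegistrationConfig | None = None
) -> RegistrationResult:
    """Coarse-to-fine B-spline registration of ``moving`` onto ``fixed``.

    ``moving`` must already be mirrored into the fixed image's laterality.
    """
    config = config or RegistrationConfig()
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving images must have identical dimensions")
    f = _to_sitk(fixed)
    m = _to_sitk(moving)

    h, w = fixed.shape
    mesh = [
        max(1, int(round(w / config.grid_spacing_finest))),
        max(1, int(round(h / config.grid_spacing_finest))),
    ]
    tx0 = sitk.BSplineTransformInitializer(f, mesh, order=3)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=config.mi_bins)
    reg.SetMetricSamplingStrategy(reg.RANDOM)
    reg.SetMetricSamplingPercentage(config.sampling_fraction, _sampling_seed(config))
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsLBFGSB(
        gradientConvergenceTolerance=1e-7,
        numberOfIterations=config.max_iterations_per_level,
        maximumNumberOfCorrections=5,
    )
    shrink = [2 ** (config.n_resolutions - 1 - i) for i in range(config.n_resolutions)]
    sigmas = [float(s // 2) for s in shrink]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel(sigmas)
    # one finest-spacing control mesh optimized through the whole pyramid;
    # parameters carry over between levels
    reg.SetInitialTransform(tx0, inPlace=True)

    identity = sitk.Transform(2, sitk.sitkIdentity)
    metric_initial = _metric_value(f, m, identity, config)
    converged = True
    try:
        transform = reg.Execute(f, m)
        metric_final = _metric_value(f, m, transform, config)
    except RuntimeError:
        transform = identity
        metric_final = metric_initial
        converged = False

    if metric_final > metric_initial:
        # optimization failed to beat the identity; keep the identity so the
        # reported metric never worsens
        transform = identity
        metric_final = metric_initial
    if converged and _jacobian_min(transform, f) <= 0:
        converged = False  # folding transform: excluded downstream

    warped = sitk.Resample(m, f, transform, sitk.sitkLinear, 0.0, sitk.sitkFloat32)
    warped_px = sitk.GetArrayFromImage(warped).astype(np.float64)
    warped_mask = None
    if moving.mask is not None:
        mm = sitk.GetImageFromArray(moving.mask.astype(np.uint8))
        wm = sitk.Resample(mm, f, transform, sitk.sitkNearestNeighbor, 0, sitk.sitkUInt8)
        warped_mask = sitk.GetArrayFromImage(wm).astype(bool)
    displacement = _displacement_field(transform, f)
    return RegistrationResult(
        transform=transform,
        warped_moving=ImageGrid(np.clip(warped_px, 0.0, None), moving.bit_depth, warped_mask),
        metric_initial=metric_initial,
        metric_final=metric_final,
        converged=converged,
        displacement=displacement,
    )


def bilateral_subtract(right: ImageGrid, warped_left: ImageGrid) -> ImageGrid:
    """Absolute difference map restricted to the joint tissue mask."""
    if right.shape != warped_left.shape:
        raise ValueError("images must have identical dimensions")
    delta = np.abs(right.pixels - warped_left.pixels)
    if right.mask is not None and warped_left.mask is not None:
        joint = right.mask & warped_left.mask
    elif right.mask is not None:
        joint = right.mask.copy()
    elif warped_left.mask is not None:
        joint = warped_left.mask.copy()
    else:
        joint = np.ones(right.shape, bool)
    delta[~joint] = 0.0
    return ImageGrid(delta, right.bit_depth, joint)
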