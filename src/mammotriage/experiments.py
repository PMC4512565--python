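"""Self-contained phantom experiments exercising the whole pipeline.

These functions generate their own synthetic inputs, run the package's
stages, and return measured quantities — registration recovery accuracy,
normalization calibration, and the end-to-end phantom cohort study that
stands in for a screening-cohort evaluation.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

from .features import build_subject_vector
from .grids import ImageGrid
from .modeling import (
    FeatureTable,
    PercentileRankNormalizer,
    RankInverseNormalNormalizer,
    SpearmanRedundancyFilter,
    evaluate_blind,
    lasso_train,
    rank_auc,
    swap_side_table,
)
from .phantom import PhantomParams, generate_cohort, generate_subject
from .pipeline import extract_cohort_features
from .registration import RegistrationConfig, register_bspline
from .segmentation import segment_breast

#: frame size used for the registration recovery experiments — a typical
#: working resolution after downsampling a digitized film
RECOVERY_SHAPE = (384, 288)


def translation_recovery(seed: int = 0, shift_px: int = 5) -> dict:
    """Register an image onto its ``shift_px``-translated copy.

    Returns the median absolute recovered displacement inside the mask and
    its error against the known shift.
    """
    h, w = RECOVERY_SHAPE
    p = PhantomParams(seed=seed, image_height=h, image_width=w)
    s = generate_subject(p)
    fixed = segment_breast(s.images[("CC", "r")]).image
    moving = ImageGrid(
        np.roll(fixed.pixels, shift_px, axis=1),
        fixed.bit_depth,
        np.roll(fixed.mask, shift_px, axis=1),
    )
    res = register_bspline(fixed, moving, RegistrationConfig(seed=seed))
    median_dx = float(np.median(np.abs(res.displacement[1][fixed.mask])))
    return {
        "median_recovered_shift_px": median_dx,
        "error_px": abs(median_dx - shift_px),
        "converged": res.converged,
    }


def sinusoidal_warp_recovery(seed: int = 0, amplitude_px: float = 10.0) -> dict:
    """Register an image onto a smooth sinusoidally warped copy.

    Returns the masked mean absolute difference before and after
    registration and their ratio (lower is better recovery).
    """
    h, w = RECOVERY_SHAPE
    p = PhantomParams(seed=seed, image_height=h, image_width=w)
    s = generate_subject(p)
    fixed = segment_breast(s.images[("CC", "r")]).image
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dx = amplitude_px * np.sin(2 * np.pi * yy / h)
    dy = amplitude_px * np.sin(2 * np.pi * xx / w)
    warped_px = map_coordinates(fixed.pixels, [yy + dy, xx + dx], order=1, mode="nearest")
    warped_mask = (
        map_coordinates(fixed.mask.astype(float), [yy + dy, xx + dx], order=1, mode="nearest") > 0.5
    )
    moving = ImageGrid(warped_px, fixed.bit_depth, warped_mask)
    res = register_bspline(fixed, moving, RegistrationConfig(seed=seed))
    pre = float(np.abs(fixed.pixels - moving.pixels)[fixed.mask].mean())
    post = float(np.abs(fixed.pixels - res.warped_moving.pixels)[fixed.mask].mean())
    return {"mad_pre": pre, "mad_post": post, "ratio": post / pre, "converged": res.converged}


def structure_counts(seed: int = 0) -> dict:
    """Extract one phantom subject and count every structural quantity."""
    from .pipeline import subject_view_stacks

    subject = generate_subject(PhantomParams(seed=seed, lesion_kind="mass"))
    stacks, _ = subject_view_stacks(subject)
    vector = build_subject_vector(stacks["CC"], stacks["MLO"])
    n_per_image = sum(1 for n in vector.index if n.split("_")[2] in ("r", "l", "d"))
    n_symmetric = sum(1 for n in vector.index if n.split("_")[2] in ("avg", "absdiff"))
    per_image_counts = {len({n for n in vector.index if n.startswith(f"{v}_")}) for v in ("CC", "MLO")}
    return {
        "images_per_view": len(stacks["CC"].images),
        "features_per_image": len(
            {n.split("_")[-1] for n in vector.index if n.startswith("CC_I_r_")}
        ),
        "per_image_features": n_per_image,
        "symmetric_features": n_symmetric,
        "total_features": int(vector.size),
        "per_view_feature_counts": sorted(per_image_counts),
    }


def cohort_study(
    seed: int = 0,
    n_hs: int = 40,
    n_cs: int = 40,
    normalization: str = "znorm",
    n_train: int = 40,
    base_params: PhantomParams | None = None,
) -> dict:
    """Full phantom study: generate, extract, normalize, select, evaluate.

    A balanced healthy/calcification cohort with unilateral lesions is run
    through every stage; the blind set's accuracy and AUC plus the
    side-swapped AUC (sensitivity analysis) are returned.
    """
    base = base_params or PhantomParams()
    cohort = generate_cohort(n_hs, n_cs, 0, base, seed=seed)
    reg_config = RegistrationConfig(seed=seed)
    table, excluded = extract_cohort_features(cohort, reg_config)

    filt = SpearmanRedundancyFilter(random_state=seed).fit(table.data)
    filtered_data = filt.transform(table.data)
    if normalization == "znorm":
        norm = RankInverseNormalNormalizer().fit(filtered_data.loc[table.labels == "HS"])
    else:
        norm = PercentileRankNormalizer().fit(filtered_data)
    normalized = FeatureTable(norm.transform(filtered_data), table.labels, normalization)

    model = lasso_train(normalized, "HSvsCS", n_train=n_train, seed=seed)
    blind = FeatureTable(
        normalized.data.loc[model.blind_ids],
        normalized.labels.loc[model.blind_ids],
        normalization,
    )
    report = evaluate_blind(model, blind, seed=seed)

    # sensitivity analysis: swap r/l values in the full raw table, then push
    # the swapped subjects through the same fitted filter and normalizer
    swapped_raw = swap_side_table(table.data)
    swapped_norm = norm.transform(filt.transform(swapped_raw))
    y = (blind.labels == "CS").to_numpy(int)
    swapped_scores = model.scores(swapped_norm.loc[model.blind_ids]).to_numpy()
    auc_swapped = rank_auc(swapped_scores, y)
    filtered = FeatureTable(filtered_data, table.labels)

    return {
        "n_subjects": len(cohort),
        "n_excluded": len(excluded),
        "n_features_after_filter": int(filtered.data.shape[1]),
        "n_selected": len(model.selected_features),
        "blind_accuracy": report.accuracy,
        "blind_accuracy_ci95": report.accuracy_ci95,
        "blind_auc": report.auc,
        "blind_auc_swapped": auc_swapped,
        "n_blind": report.n_test,
        "model": model,
        "evaluation": report,
    }
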