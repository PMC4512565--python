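"""Feature bank: hand examples, brute-force oracles, vector assembly."""

import numpy as np
import pandas as pd
import pytest

from mammotriage.features import (
    EmptyMaskError,
    FEATURE_NAMES,
    build_subject_vector,
    build_view_stack,
    extract_image_features,
    mask_perimeter,
    morphology_features,
    shape_features,
    signal_features,
    quantize_masked_values,
)
from mammotriage.filters import FilterConfig
from mammotriage.grids import ImageGrid

from oracles import all_features_loops, morphology_loops, shape_loops, signal_loops


def _masked(img, mask=None):
    img = np.asarray(img, float)
    mask = np.ones(img.shape, bool) if mask is None else np.asarray(mask, bool)
    return ImageGrid(img, bit_depth=12, mask=mask)


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

def test_single_pixel_shape():
    mask = np.zeros((5, 5), bool)
    mask[2, 3] = True
    f = shape_features(mask)
    assert f["area"] == 1
    assert mask_perimeter(mask) == 4
    assert f["compactness"] == 16.0
    assert f["elongation"] == 1.0
    assert (f["centroid_x"], f["centroid_y"]) == (3.0, 2.0)
    assert (f["scatter_xx"], f["scatter_xy"], f["scatter_yy"]) == (0.0, 0.0, 0.0)


def test_full_square_centroid():
    mask = np.ones((3, 3), bool)
    f = shape_features(mask)
    assert (f["centroid_x"], f["centroid_y"]) == (1.0, 1.0)


def test_shape_matches_loops_on_random_blobs(rng):
    for _ in range(5):
        mask = rng.uniform(size=(8, 8)) > 0.5
        if not mask.any():
            continue
        got = shape_features(mask)
        want = shape_loops(mask)
        np.testing.assert_allclose(list(got.values()), want, rtol=1e-12)


def test_empty_mask_raises():
    with pytest.raises(EmptyMaskError):
        shape_features(np.zeros((4, 4), bool))


# ---------------------------------------------------------------------------
# signal
# ---------------------------------------------------------------------------

def test_constant_image_signal_degenerates():
    f = signal_features(np.full(50, 7, dtype=int))
    assert f["mean"] == 7
    assert f["variance"] == 0
    assert f["entropy"] == 0
    assert f["dynamic_range"] == 0
    assert f["z_mean"] == 0 and f["skewness"] == 0 and f["kurtosis"] == 0


def test_two_value_hand_example():
    f = signal_features(np.array([1, 1, 3, 3]))
    assert f["mean"] == pytest.approx(2.0)
    assert f["variance"] == pytest.approx(1.0)
    assert f["energy"] == pytest.approx(5.0)
    assert f["dynamic_range"] == 2.0
    assert f["skewness"] == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_signal_matches_raw_list_oracle(seed):
    rng = np.random.default_rng(seed)
    values = rng.integers(0, 256, size=60)
    got = list(signal_features(values).values())
    want = signal_loops([int(v) for v in values])
    np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-12)


def test_quantization_modes(rng):
    img = _masked(rng.uniform(-3.0, 5.0, (8, 8)))
    q = quantize_masked_values(img, "minmax1024")
    assert q.min() == 0 and q.max() == 1023
    flat = _masked(np.full((4, 4), 2.5))
    assert np.all(quantize_masked_values(flat, "minmax1024") == 0)


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

def test_single_pixel_morphology():
    img = np.zeros((6, 6))
    img[3, 2] = 5.0
    mask = img > 0
    f = morphology_features(_masked(img, mask))
    assert f["signal_mass"] == 5.0
    assert (f["signal_centroid_x"], f["signal_centroid_y"]) == (2.0, 3.0)
    assert f["signal_scatter_xx"] == 0.0 and f["signal_scatter_yy"] == 0.0


def test_constant_image_surface_flat_limit():
    img = np.full((5, 5), 9.0)
    f = morphology_features(_masked(img))
    assert f["signal_surface"] == pytest.approx(25 / 2.0)


def test_zero_mass_returns_zero_centroid():
    f = morphology_features(_masked(np.zeros((4, 4))))
    assert f["signal_mass"] == 0.0
    assert f["signal_centroid_x"] == 0.0 and f["signal_centroid_y"] == 0.0


def test_morphology_matches_loops(rng):
    for _ in range(5):
        img = np.round(rng.uniform(0, 100, (8, 8)))
        mask = rng.uniform(size=(8, 8)) > 0.3
        if not mask.any():
            continue
        got = list(morphology_features(_masked(img, mask)).values())
        want = morphology_loops(img, mask)
        np.testing.assert_allclose(got, want, rtol=1e-12)


# ---------------------------------------------------------------------------
# per-image extraction and assembly
# ---------------------------------------------------------------------------

def test_extract_has_43_entries_and_is_deterministic(rng):
    img = np.round(rng.uniform(0, 4095, (12, 12)))
    mask = np.zeros((12, 12), bool)
    mask[2:10, 3:11] = True
    a = extract_image_features(_masked(img, mask))
    b = extract_image_features(_masked(img.copy(), mask.copy()))
    assert len(a) == 43 == len(FEATURE_NAMES)
    assert list(a) == [f"f{k:02d}" for k in range(1, 44)]
    assert a == b


def test_extract_requires_mask(rng):
    img = ImageGrid(rng.uniform(0, 10, (8, 8)), bit_depth=12)
    with pytest.raises(ValueError):
        extract_image_features(img)


def test_full_extraction_matches_oracle(rng):
    """All 43 features agree with double-loop oracles on masked patches."""
    for _ in range(10):
        img = np.round(rng.uniform(0, 255, (8, 8)))
        mask = rng.uniform(size=(8, 8)) > 0.4
        if mask.sum() < 3:
            continue
        got = list(extract_image_features(_masked(img, mask), "integer").values())
        want = all_features_loops(img, mask)
        np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-12)


def _identity_stack(view, rng):
    """A stack whose left and right images are identical (self-registered)."""
    img = np.round(rng.uniform(100, 1000, (24, 24)))
    mask = np.zeros((24, 24), bool)
    mask[4:20, 4:20] = True
    grid = ImageGrid(np.where(mask, img, 0.0), 12, mask)
    return build_view_stack(view, grid, grid.copy(), grid.copy(), FilterConfig())


def test_view_stack_structure(rng):
    stack = _identity_stack("CC", rng)
    assert len(stack.images) == 15
    assert {v for v, _ in stack.images} == {"I", "H", "L", "S", "F"}
    assert {s for _, s in stack.images} == {"r", "l", "d"}
    # identical sides: the subtraction image is identically zero
    assert np.all(stack.images[("I", "d")].pixels == 0)


def test_subject_vector_layout_and_symmetry(rng):
    cc = _identity_stack("CC", rng)
    mlo = _identity_stack("MLO", rng)
    vec = build_subject_vector(cc, mlo)
    assert len(vec) == 2150
    per_image = [n for n in vec.index if n.split("_")[2] in ("r", "l", "d")]
    symmetric = [n for n in vec.index if n.split("_")[2] in ("avg", "absdiff")]
    assert len(per_image) == 1290
    assert len(symmetric) == 860
    # identical left/right images: every absolute-difference feature is zero
    absdiff = vec[[n for n in vec.index if "_absdiff_" in n]]
    assert np.all(absdiff.to_numpy() == 0.0)
    # and every avg feature equals the right-side feature
    for view, variant in (("CC", "I"), ("MLO", "S")):
        for k in (1, 17, 43):
            r = vec[f"{view}_{variant}_r_f{k:02d}"]
            assert vec[f"{view}_{variant}_avg_f{k:02d}"] == pytest.approx(r)


def test_symmetric_feature_swap_invariance(rng):
    """avg and absdiff are symmetric in the left/right arguments."""
    img_a = np.round(rng.uniform(100, 1000, (24, 24)))
    img_b = np.round(rng.uniform(100, 1000, (24, 24)))
    mask = np.zeros((24, 24), bool)
    mask[4:20, 4:20] = True
    ga = ImageGrid(np.where(mask, img_a, 0.0), 12, mask)
    gb = ImageGrid(np.where(mask, img_b, 0.0), 12, mask)
    cfg = FilterConfig()
    v1 = build_subject_vector(
        build_view_stack("CC", ga, gb, gb, cfg), build_view_stack("MLO", ga, gb, gb, cfg)
    )
    v2 = build_subject_vector(
        build_view_stack("CC", gb, ga, ga, cfg), build_view_stack("MLO", gb, ga, ga, cfg)
    )
    sym = [n for n in v1.index if "_avg_" in n or "_absdiff_" in n]
    drop = [n for n in sym if n.split("_")[1] == "I" and "_absdiff_" not in n and "_avg_" not in n]
    assert not drop
    kept1 = v1[sym]
    kept2 = v2[sym]
    # subtraction maps |a-b| are identical either way, and avg/absdiff are
    # symmetric functions of the per-side features
    pd.testing.assert_series_equal(kept1, kept2)
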