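"""Correlation filter, normalizations, LASSO, evaluation, triage arithmetic."""

import numpy as np
import pandas as pd
import pytest

from mammotriage.modeling import (
    FeatureTable,
    LassoTriageModel,
    PercentileRankNormalizer,
    RankInverseNormalNormalizer,
    correlation_filter,
    evaluate_blind,
    independent_triage_fractions,
    lasso_train,
    prank_normalize,
    rank_auc,
    roc_points,
    spearman_matrix,
    swap_side_features,
    swap_side_table,
    triage_groups,
    znormalize_int,
)

from oracles import auc_pairs


def _table(data: np.ndarray, labels, names=None) -> FeatureTable:
    names = names or [f"x{i}" for i in range(data.shape[1])]
    ids = [f"s{i}" for i in range(data.shape[0])]
    return FeatureTable(pd.DataFrame(data, index=ids, columns=names), pd.Series(labels, index=ids))


# ---------------------------------------------------------------------------
# correlation filter
# ---------------------------------------------------------------------------

def test_duplicated_column_one_survives(rng):
    x = rng.normal(size=(30, 1))
    data = np.hstack([x, x, rng.normal(size=(30, 1))])
    t = _table(data, ["HS"] * 15 + ["CS"] * 15, ["a", "b", "c"])
    out = correlation_filter(t, seed=0)
    assert out.data.shape[1] == 2
    assert "c" in out.data.columns
    assert ("a" in out.data.columns) != ("b" in out.data.columns)


def test_independent_noise_columns_all_survive(rng):
    data = rng.normal(size=(200, 25))
    t = _table(data, ["HS"] * 100 + ["CS"] * 100)
    out = correlation_filter(t, seed=1)
    assert out.data.shape[1] == 25


def test_filter_idempotent_and_no_residual_pairs(rng):
    base = rng.normal(size=(40, 6))
    data = np.hstack([base, base[:, :3] + rng.normal(0, 1e-6, (40, 3))])
    t = _table(data, ["HS"] * 20 + ["CS"] * 20)
    once = correlation_filter(t, seed=3)
    twice = correlation_filter(once, seed=4)
    assert list(once.data.columns) == list(twice.data.columns)
    rho = spearman_matrix(once.data.to_numpy(float))
    np.fill_diagonal(rho, 0.0)
    assert np.abs(rho).max() <= 0.96


def test_constant_feature_retained(rng):
    data = np.hstack([np.ones((20, 1)), rng.normal(size=(20, 2))])
    t = _table(data, ["HS"] * 10 + ["CS"] * 10, ["const", "a", "b"])
    out = correlation_filter(t, seed=0)
    assert "const" in out.data.columns


# ---------------------------------------------------------------------------
# normalizations
# ---------------------------------------------------------------------------

def test_prank_reference_median_and_extremes(rng):
    ref = pd.DataFrame({"f": rng.normal(size=45)})
    norm = PercentileRankNormalizer().fit(ref)
    med = float(np.median(ref["f"]))
    out = norm.transform(pd.DataFrame({"f": [med, ref["f"].min() - 10, ref["f"].max() + 10]}))
    assert out["f"].iloc[0] == pytest.approx(0.5, abs=1.0 / 45)
    assert out["f"].iloc[1] == 0.0
    assert out["f"].iloc[2] == 1.0


def test_prank_monotone_transform_invariance(rng):
    ref = pd.DataFrame({"f": rng.normal(size=31)})
    vals = pd.DataFrame({"f": rng.normal(size=10)})
    a = PercentileRankNormalizer().fit(ref).transform(vals)
    b = PercentileRankNormalizer().fit(np.exp(ref)).transform(np.exp(vals))
    pd.testing.assert_frame_equal(a, b)


def test_rank_int_reference_calibration(rng):
    """Blom scores of a 45-subject healthy reference: mean ~0, sd ~1."""
    ref = pd.DataFrame({"f": rng.normal(50, 7, size=45)})
    norm = RankInverseNormalNormalizer().fit(ref)
    z = norm.transform(ref)["f"].to_numpy()
    assert abs(z.mean()) <= 0.05
    assert abs(z.std(ddof=1) - 1.0) <= 0.15


def test_rank_int_median_and_order(rng):
    ref = pd.DataFrame({"f": rng.normal(size=45)})
    norm = RankInverseNormalNormalizer().fit(ref)
    med = float(np.median(ref["f"]))
    assert norm.transform(pd.DataFrame({"f": [med]}))["f"].iloc[0] == pytest.approx(0.0, abs=1e-9)
    vals = rng.normal(0, 3, size=30)
    z = norm.transform(pd.DataFrame({"f": vals}))["f"].to_numpy()
    assert np.all(np.sign(np.diff(z[np.argsort(vals)])) > 0)


def test_rank_int_needs_three_reference_subjects():
    with pytest.raises(ValueError):
        RankInverseNormalNormalizer().fit(pd.DataFrame({"f": [1.0, 2.0]}))


def test_normalizations_preserve_univariate_auc(rng):
    """Both maps are strictly monotone, so each feature's AUC is unchanged."""
    n = 60
    labels = np.array(["HS"] * 25 + ["CS"] * 35)
    data = rng.normal(size=(n, 4)) + 1.2 * (labels == "CS")[:, None] * rng.uniform(0.5, 1.5, 4)
    t = _table(data, list(labels))
    y = (t.labels == "CS").to_numpy(int)
    pr = prank_normalize(t, t)
    zn = znormalize_int(t, t.restrict("HS"))
    for c in t.data.columns:
        auc0 = rank_auc(t.data[c].to_numpy(), y)
        assert rank_auc(pr.data[c].to_numpy(), y) == pytest.approx(auc0, abs=1e-12)
        assert rank_auc(zn.data[c].to_numpy(), y) == pytest.approx(auc0, abs=1e-12)


def test_znormalize_requires_healthy_reference(rng):
    t = _table(rng.normal(size=(10, 2)), ["HS"] * 5 + ["CS"] * 5)
    with pytest.raises(ValueError):
        znormalize_int(t, t)  # mixed-label reference refused


# ---------------------------------------------------------------------------
# LASSO training
# ---------------------------------------------------------------------------

def _signal_table(rng, n=40, p=12, effect=2.0):
    labels = ["HS"] * (n // 2) + ["CS"] * (n // 2)
    data = rng.normal(size=(n, p))
    data[:, 0] += effect * (np.array(labels) == "CS")
    return _table(data, labels)


def test_huge_penalty_gives_intercept_only(rng):
    t = _signal_table(rng)
    spec = lasso_train(t, "HSvsCS", n_train=20, seed=0, lambda_grid=np.array([1e9]))
    assert spec.selected_features == []
    assert spec.intercept == pytest.approx(0.5, abs=0.2)


def test_zero_penalty_matches_least_squares(rng):
    t = _signal_table(rng, n=20, p=5)
    spec = lasso_train(t, "HSvsCS", n_train=20, seed=0, lambda_grid=np.array([0.0]))
    X = t.data.to_numpy(float)
    y = (t.labels == "CS").to_numpy(float)
    # training sample is the whole table here, so OLS is the oracle
    ids = list(t.data.index)
    order = [ids.index(i) for i in spec.train_ids]
    A = np.column_stack([np.ones(20), X[order]])
    beta, *_ = np.linalg.lstsq(A, y[order], rcond=None)
    assert spec.intercept == pytest.approx(beta[0], abs=1e-6)
    coefs = np.array([spec.coefficients.get(c, 0.0) for c in t.data.columns])
    np.testing.assert_allclose(coefs, beta[1:], atol=1e-6)


def test_planted_signal_recovered_single_replicate(rng):
    n, p = 100, 203
    labels = ["HS"] * 50 + ["CS"] * 50
    data = rng.normal(size=(n, p))
    for k in range(3):
        data[:, k] += 2.0 * (np.array(labels) == "CS")
    t = _table(data, labels)
    spec = lasso_train(t, "HSvsCS", n_train=100, seed=0)
    assert {"x0", "x1", "x2"} <= set(spec.selected_features)


def test_degenerate_training_class_raises(rng):
    t = _table(rng.normal(size=(10, 3)), ["HS"] * 8 + ["CS"] * 2)
    with pytest.raises(ValueError):
        lasso_train(t, "HSvsCS", n_train=10, seed=0)


def test_sklearn_estimator_wrapper(rng):
    t = _signal_table(rng, n=30)
    est = LassoTriageModel(n_train=20, random_state=0)
    y = (t.labels == "CS").to_numpy(int)
    est.fit(t.data, y)
    assert len(est.blind_ids_) == 10
    preds = est.predict(t.data.loc[est.blind_ids_])
    assert set(preds) <= {0, 1}
    params = est.get_params()
    assert params["n_train"] == 20


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _model_for_scores(scores, ids):
    from mammotriage.modeling import ModelSpec

    return ModelSpec(
        normalization="raw",
        contrast="HSvsCS",
        selected_features=["s"],
        coefficients={"s": 1.0},
        intercept=0.0,
        decision_threshold=0.5,
        lambda_=0.1,
        train_ids=[],
        blind_ids=list(ids),
        loocv_accuracy=1.0,
    )


def test_perfect_separation_evaluation():
    ids = ["a", "b", "c", "d"]
    table = FeatureTable(
        pd.DataFrame({"s": [0.1, 0.2, 0.8, 0.9]}, index=ids),
        pd.Series(["HS", "HS", "CS", "CS"], index=ids),
    )
    rep = evaluate_blind(_model_for_scores(None, ids), table)
    assert rep.auc == 1.0
    assert rep.accuracy == 1.0
    assert rep.roc[0] == (0.0, 0.0) and rep.roc[-1] == (1.0, 1.0)


def test_auc_matches_pair_enumeration():
    scores = [0.9, 0.2, 0.8, 0.1]
    labels = [0, 0, 1, 1]
    assert rank_auc(np.array(scores), np.array(labels)) == pytest.approx(
        auc_pairs(scores, labels)
    )
    assert rank_auc(np.array(scores), np.array(labels)) == 0.25


def test_tied_scores_auc_half():
    assert rank_auc(np.ones(6), np.array([0, 1, 0, 1, 0, 1])) == 0.5


def test_roc_monotone(rng):
    scores = rng.normal(size=50)
    labels = rng.uniform(size=50) > 0.5
    pts = roc_points(scores, labels)
    fpr = [p[0] for p in pts]
    tpr = [p[1] for p in pts]
    assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)
    assert all(b >= a for a, b in zip(tpr, tpr[1:]))
    assert all(b >= a for a, b in zip(fpr, fpr[1:]))


def test_single_class_test_set_rejected():
    ids = ["a", "b"]
    table = FeatureTable(
        pd.DataFrame({"s": [0.1, 0.2]}, index=ids), pd.Series(["HS", "HS"], index=ids)
    )
    with pytest.raises(ValueError):
        evaluate_blind(_model_for_scores(None, ids), table)


# ---------------------------------------------------------------------------
# side swap
# ---------------------------------------------------------------------------

def _toy_vector():
    names = [
        "CC_I_r_f01",
        "CC_I_l_f01",
        "CC_I_d_f01",
        "CC_I_avg_f01",
        "CC_I_absdiff_f01",
        "MLO_H_r_f07",
        "MLO_H_l_f07",
    ]
    return pd.Series([1.0, 2.0, 3.0, 1.5, 1.0, 10.0, 20.0], index=names)


def test_swap_exchanges_sides_only():
    v = _toy_vector()
    s = swap_side_features(v)
    assert s["CC_I_r_f01"] == 2.0 and s["CC_I_l_f01"] == 1.0
    assert s["MLO_H_r_f07"] == 20.0 and s["MLO_H_l_f07"] == 10.0
    assert s["CC_I_d_f01"] == 3.0
    assert s["CC_I_avg_f01"] == 1.5 and s["CC_I_absdiff_f01"] == 1.0


def test_swap_involution_and_table_variant():
    v = _toy_vector()
    pd.testing.assert_series_equal(swap_side_features(swap_side_features(v)), v)
    df = pd.DataFrame([v, v * 2])
    swapped = swap_side_table(df)
    assert list(swapped.columns) == list(df.columns)
    assert swapped.iloc[0]["CC_I_r_f01"] == 2.0


def test_swap_fixed_point_on_symmetric_vector():
    v = _toy_vector()
    v["CC_I_l_f01"] = v["CC_I_r_f01"]
    v["MLO_H_l_f07"] = v["MLO_H_r_f07"]
    pd.testing.assert_series_equal(swap_side_features(v), v)


# ---------------------------------------------------------------------------
# triage
# ---------------------------------------------------------------------------

def test_independence_arithmetic():
    high, low = independent_triage_fractions(0.9, 0.9, 0.5, 0.4)
    assert high == pytest.approx(0.19)
    assert low == pytest.approx(0.20)


def test_triage_perfect_model_flags_diseased(rng):
    n = 100
    diseased = np.arange(n) < 30
    scores_perfect = np.where(diseased, 1.0, 0.0) + rng.normal(0, 0.01, n)
    scores_other = rng.uniform(size=n)
    diseased_other = rng.uniform(size=n) < 0.3
    rep = triage_groups(scores_perfect, diseased, scores_other, diseased_other)
    flagged = scores_perfect >= rep.calc.specificity_cutoff
    assert flagged[diseased].all()
    assert rep.calc.achieved_specificity >= 0.9
    assert 0.0 <= rep.observed_high_fraction <= 1.0


def test_triage_unachievable_target_flagged():
    scores = np.array([0.5] * 10)  # all tied: no cutoff reaches 90% specificity
    diseased = np.array([True] * 5 + [False] * 5)
    rep = triage_groups(scores, diseased, scores, diseased)
    assert not rep.calc.target_met
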