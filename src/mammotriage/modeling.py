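"""Feature-table preprocessing, LASSO triage models, and triage arithmetic.

The modeling stage works on a subjects x features table:

1. a Spearman redundancy filter drops one member (chosen at random) of
   every feature pair correlated above |rho| = 0.96;
2. the table is normalized either by percentile rank against a reference
   cohort (p-rank) or by the rank-based inverse normal transform fitted on
   the healthy subjects (z-normalization);
3. an L1-penalized linear model of the 0/1 class label is fitted on a
   class-balanced training sample, with the penalty chosen to maximize
   leave-one-out cross-validated accuracy at a 0.5 decision threshold;
   its nonzero coefficients are the selected features;
4. the held-out subjects form the blind test set on which accuracy
   (with a bootstrap CI), ROC and rank-based AUC are reported.

A side-swap sensitivity analysis exchanges every left/right per-image
feature with its contralateral counterpart, and the triage arithmetic
combines the calcification and mass models' sensitivity/specificity
cutoffs into high/low priority reading groups.

All estimators follow the scikit-learn fit/transform contract and compose
with sklearn pipelines; the module-level functions are thin wrappers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import Lasso, lasso_path
from sklearn.utils import check_random_state

SPEARMAN_THRESHOLD = 0.96
_PER_IMAGE_RE = re.compile(r"^(CC|MLO)_([IHLSF])_(r|l)_(f\d{2})$")


# ---------------------------------------------------------------------------
# feature table container
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Subjects x named features plus per-subject class labels."""

    data: pd.DataFrame  # index: subject ids, columns: feature names
    labels: pd.Series  # index-aligned, values in {"HS", "CS", "MS"}
    normalization_state: str = "raw"  # raw | prank | znorm

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValueError("duplicated feature names")
        self.labels = self.labels.reindex(self.data.index)
        if self.labels.isna().any():
            raise ValueError("every subject needs a label")

    def restrict(self, label: str) -> "FeatureTable":
        keep = self.labels == label
        return FeatureTable(self.data.loc[keep], self.labels.loc[keep], self.normalization_state)

    def contrast(self, positive: str, negative: str = "HS") -> "FeatureTable":
        keep = self.labels.isin([positive, negative])
        return FeatureTable(self.data.loc[keep], self.labels.loc[keep], self.normalization_state)


# ---------------------------------------------------------------------------
# Spearman redundancy filter
# ---------------------------------------------------------------------------

class SpearmanRedundancyFilter(BaseEstimator, TransformerMixin):
    """Drop one random member of every feature pair with |rho| > threshold.

    Pairs are scanned greedily in column order; a pair is only examined if
    both members are still alive, and the survivor is chosen uniformly at
    random with the seeded generator.  Constant features have undefined
    rho, are treated as rho = 0, and are always retained.
    """

    def __init__(self, threshold: float = SPEARMAN_THRESHOLD, random_state=None):
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if len(X) < 2:
            raise ValueError("need at least 2 subjects to measure correlation")
        rng = check_random_state(self.random_state)
        rho = spearman_matrix(X.to_numpy(dtype=np.float64))
        n = rho.shape[0]
        alive = np.ones(n, dtype=bool)
        for i in range(n):
            if not alive[i]:
                continue
            for j in range(i + 1, n):
                if not (alive[i] and alive[j]):
                    continue
                if abs(rho[i, j]) > self.threshold:
                    drop = (i, j)[rng.randint(2)]
                    alive[drop] = False
                if not alive[i]:
                    break
        self.support_ = alive
        self.selected_features_ = list(X.columns[alive])
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        return X.loc[:, self.selected_features_]

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y).transform(X)


def spearman_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise Spearman rho; constant columns get rho = 0 everywhere."""
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    sd = ranks.std(axis=0)
    constant = sd == 0
    ranks = ranks - ranks.mean(axis=0)
    denom = np.sqrt((ranks**2).sum(axis=0))
    denom[constant] = 1.0
    normed = ranks / denom
    rho = normed.T @ normed
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    return rho


def correlation_filter(
    table: FeatureTable, threshold: float = SPEARMAN_THRESHOLD, seed: int = 0
) -> FeatureTable:
    filt = SpearmanRedundancyFilter(threshold=threshold, random_state=seed)
    return FeatureTable(filt.fit_transform(table.data), table.labels, table.normalization_state)


# ---------------------------------------------------------------------------
# normalizations
# ---------------------------------------------------------------------------

class PercentileRankNormalizer(BaseEstimator, TransformerMixin):
    """Percentile rank against a reference cohort, midpoint convention.

    A value maps to (count of reference values strictly below it + half the
    count equal to it) / n, so outputs lie in [0, 1] and any strictly
    monotone transform applied jointly to values and reference leaves the
    output unchanged.
    """

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if len(X) == 0:
            raise ValueError("empty reference table")
        self.feature_names_in_ = list(X.columns)
        self.reference_sorted_ = {c: np.sort(X[c].to_numpy(np.float64)) for c in X.columns}
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        if list(X.columns) != self.feature_names_in_:
            X = X.loc[:, self.feature_names_in_]
        out = {}
        for c in self.feature_names_in_:
            ref = self.reference_sorted_[c]
            vals = X[c].to_numpy(np.float64)
            below = np.searchsorted(ref, vals, side="left")
            upto = np.searchsorted(ref, vals, side="right")
            out[c] = (below + upto) / (2.0 * ref.size)
        return pd.DataFrame(out, index=X.index)[self.feature_names_in_]


class RankInverseNormalNormalizer(BaseEstimator, TransformerMixin):
    """Rank-based inverse normal transform fitted on a healthy reference.

    Reference values receive Blom scores Phi^-1((r - 3/8)/(n + 1/4)); other
    values pass through the piecewise-linear interpolant of the reference
    (value -> Blom score) map.  Outside the reference range the map is
    continued with the Gaussian-tail slope 1/SD of the reference (the
    slope of the ideal inverse-normal map for a Gaussian reference), so it
    stays strictly monotone with bounded scale, and rank order — hence
    every univariate AUC — is preserved exactly.
    """

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if len(X) < 3:
            raise ValueError("rank-INT needs at least 3 healthy reference subjects")
        n = len(X)
        self.feature_names_in_ = list(X.columns)
        self.maps_ = {}
        for c in X.columns:
            vals = X[c].to_numpy(np.float64)
            ranks = stats.rankdata(vals)  # average ranks for ties
            scores = ndtri((ranks - 3.0 / 8.0) / (n + 0.25))
            uniq, inverse = np.unique(vals, return_inverse=True)
            mean_scores = np.zeros(uniq.size)
            np.add.at(mean_scores, inverse, scores)
            counts = np.bincount(inverse)
            mean_scores /= counts
            sd = float(vals.std(ddof=1))
            self.maps_[c] = (uniq, mean_scores, sd)
        return self

    @staticmethod
    def _apply(xs: np.ndarray, xp: np.ndarray, fp: np.ndarray, sd: float) -> np.ndarray:
        if xp.size == 1 or sd == 0:
            # constant reference feature: no scale to set; keep the raw
            # offset so distinct values stay distinct (order preserved)
            return xs - xp[0]
        out = np.interp(xs, xp, fp)
        tail_slope = 1.0 / sd
        below = xs < xp[0]
        above = xs > xp[-1]
        out[below] = fp[0] + (xs[below] - xp[0]) * tail_slope
        out[above] = fp[-1] + (xs[above] - xp[-1]) * tail_slope
        return out

    def transform(self, X):
        X = pd.DataFrame(X)
        if list(X.columns) != self.feature_names_in_:
            X = X.loc[:, self.feature_names_in_]
        out = {}
        for c in self.feature_names_in_:
            xp, fp, sd = self.maps_[c]
            out[c] = self._apply(X[c].to_numpy(np.float64), xp, fp, sd)
        return pd.DataFrame(out, index=X.index)[self.feature_names_in_]


def prank_normalize(table: FeatureTable, reference: FeatureTable) -> FeatureTable:
    norm = PercentileRankNormalizer().fit(reference.data)
    return FeatureTable(norm.transform(table.data), table.labels, "prank")


def znormalize_int(table: FeatureTable, healthy_reference: FeatureTable) -> FeatureTable:
    if not (healthy_reference.labels == "HS").all():
        raise ValueError("z-normalization reference must contain healthy subjects only")
    norm = RankInverseNormalNormalizer().fit(healthy_reference.data)
    return FeatureTable(norm.transform(table.data), table.labels, "znorm")


# ---------------------------------------------------------------------------
# LASSO model selection with LOOCV calibration
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """A fitted triage model: selected features, coefficients, split."""

    normalization: str
    contrast: str
    selected_features: list[str]
    coefficients: dict[str, float]
    intercept: float
    decision_threshold: float
    lambda_: float
    train_ids: list[str]
    blind_ids: list[str]
    loocv_accuracy: float

    def scores(self, data: pd.DataFrame) -> pd.Series:
        s = pd.Series(self.intercept, index=data.index, dtype=float)
        for name, coef in self.coefficients.items():
            s += coef * data[name]
        return s

    def predict(self, data: pd.DataFrame) -> pd.Series:
        return (self.scores(data) >= self.decision_threshold).astype(int)

    def to_dict(self) -> dict:
        return {
            "normalization": self.normalization,
            "contrast": self.contrast,
            "selected_features": self.selected_features,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "decision_threshold": self.decision_threshold,
            "lambda": self.lambda_,
            "train_ids": self.train_ids,
            "blind_ids": self.blind_ids,
            "loocv_accuracy": self.loocv_accuracy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            normalization=d["normalization"],
            contrast=d["contrast"],
            selected_features=list(d["selected_features"]),
            coefficients=dict(d["coefficients"]),
            intercept=float(d["intercept"]),
            decision_threshold=float(d["decision_threshold"]),
            lambda_=float(d["lambda"]),
            train_ids=list(d["train_ids"]),
            blind_ids=list(d["blind_ids"]),
            loocv_accuracy=float(d["loocv_accuracy"]),
        )


def _loocv_accuracy_path(X: np.ndarray, y: np.ndarray, alphas: np.ndarray, threshold: float) -> np.ndarray:
    """LOOCV accuracy of the squared-error LASSO for each penalty value."""
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    n = len(y)
    correct = np.zeros(alphas.size)
    nonzero = alphas > 0
    for i in range(n):
        keep = np.ones(n, bool)
        keep[i] = False
        Xt, yt = X[keep], y[keep]
        xm = Xt.mean(axis=0)
        ym = yt.mean()
        preds = np.empty(alphas.size)
        if nonzero.any():
            with warnings.catch_warnings():
                # the scan only needs the predicted sign; residual duality
                # gaps at small penalties are irrelevant here
                warnings.simplefilter("ignore", ConvergenceWarning)
                _, coefs, _ = lasso_path(Xt - xm, yt - ym, alphas=alphas[nonzero])
            preds[nonzero] = (X[i] - xm) @ coefs + ym  # one prediction per alpha
        if (~nonzero).any():  # unpenalized limit: ordinary least squares
            beta, *_ = np.linalg.lstsq(Xt - xm, yt - ym, rcond=None)
            preds[~nonzero] = (X[i] - xm) @ beta + ym
        correct += (preds >= threshold) == (y[i] >= 0.5)
    return correct / n


def lasso_train(
    table: FeatureTable,
    contrast: str,
    n_train: int = 100,
    seed: int = 0,
    lambda_grid: np.ndarray | None = None,
    decision_threshold: float = 0.5,
) -> ModelSpec:
    """Balanced-sample LASSO selection with LOOCV-calibrated penalty.

    ``contrast`` is ``"HSvsCS"`` or ``"HSvsMS"``; the positive (diseased)
    class is coded 1, healthy 0.  A seeded class-balanced sample of
    ``n_train`` subjects is drawn for training; everyone else in the two
    classes is the blind test set.  The penalty maximizing LOOCV accuracy
    at the 0.5 threshold is kept (ties break toward the sparser model).
    """
    if contrast not in ("HSvsCS", "HSvsMS"):
        raise ValueError("contrast must be 'HSvsCS' or 'HSvsMS'")
    positive = contrast[4:]
    sub = table.contrast(positive)
    y_all = (sub.labels == positive).astype(int)
    per_class = n_train // 2
    rng = np.random.default_rng(seed)
    ids = {}
    for cls, want in (("HS", n_train - per_class), (positive, per_class)):
        pool = list(sub.data.index[sub.labels == cls])
        if len(pool) < want:
            raise ValueError(f"class {cls} has {len(pool)} subjects, need {want} for training")
        ids[cls] = list(rng.choice(pool, size=want, replace=False))
    train_ids = ids["HS"] + ids[positive]
    blind_ids = [i for i in sub.data.index if i not in set(train_ids)]
    Xt = sub.data.loc[train_ids].to_numpy(np.float64)
    yt = y_all.loc[train_ids].to_numpy(np.float64)
    if len(np.unique(yt)) < 2:
        raise ValueError("degenerate training sample: a single class")

    if lambda_grid is None:
        # standard lasso alpha_max for the centered problem, log grid below it
        xc = Xt - Xt.mean(axis=0)
        yc = yt - yt.mean()
        alpha_max = np.max(np.abs(xc.T @ yc)) / len(yt)
        lambda_grid = np.geomspace(alpha_max, alpha_max * 1e-3, 15)
    lambda_grid = np.sort(np.asarray(lambda_grid, np.float64))[::-1]

    acc = _loocv_accuracy_path(Xt, yt, lambda_grid, decision_threshold)
    best = int(np.argmax(acc))  # argmax takes the first = largest penalty on ties
    alpha = float(lambda_grid[best])

    if alpha > 0:
        model = Lasso(alpha=alpha, max_iter=50_000)
        model.fit(Xt, yt)
        coef = model.coef_
        intercept = float(model.intercept_)
    else:  # unpenalized limit: ordinary least squares
        A = np.column_stack([np.ones(len(yt)), Xt])
        beta, *_ = np.linalg.lstsq(A, yt, rcond=None)
        intercept, coef = float(beta[0]), beta[1:]
    names = list(sub.data.columns)
    nonzero = {names[k]: float(coef[k]) for k in np.nonzero(coef)[0]}
    return ModelSpec(
        normalization=table.normalization_state,
        contrast=contrast,
        selected_features=sorted(nonzero),
        coefficients=nonzero,
        intercept=intercept,
        decision_threshold=decision_threshold,
        lambda_=alpha,
        train_ids=list(train_ids),
        blind_ids=blind_ids,
        loocv_accuracy=float(acc[best]),
    )


class LassoTriageModel(BaseEstimator):
    """sklearn-style wrapper around :func:`lasso_train`.

    ``fit(X, y)`` takes a features DataFrame and 0/1 (or boolean) labels,
    draws the seeded class-balanced training sample internally, calibrates
    the penalty by LOOCV accuracy, and records the held-out subjects in
    ``blind_ids_``.  ``decision_function`` returns the linear score;
    ``predict`` thresholds it at 0.5.
    """

    def __init__(
        self,
        n_train: int = 100,
        lambda_grid=None,
        decision_threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.n_train = n_train
        self.lambda_grid = lambda_grid
        self.decision_threshold = decision_threshold
        self.random_state = random_state

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = pd.Series(np.asarray(y).astype(int), index=X.index)
        labels = y.map({0: "HS", 1: "CS"})
        table = FeatureTable(X, labels)
        spec = lasso_train(
            table,
            "HSvsCS",
            n_train=self.n_train,
            seed=self.random_state,
            lambda_grid=self.lambda_grid,
            decision_threshold=self.decision_threshold,
        )
        self.model_spec_ = spec
        self.selected_features_ = spec.selected_features
        self.coef_ = np.array([spec.coefficients.get(c, 0.0) for c in X.columns])
        self.intercept_ = spec.intercept
        self.lambda_ = spec.lambda_
        self.train_ids_ = spec.train_ids
        self.blind_ids_ = spec.blind_ids
        return self

    def decision_function(self, X):
        X = pd.DataFrame(X)
        return self.model_spec_.scores(X).to_numpy()

    def predict(self, X):
        return (self.decision_function(X) >= self.decision_threshold).astype(int)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    accuracy: float
    accuracy_ci95: tuple[float, float]
    auc: float
    roc: list[tuple[float, float]]  # (fpr, tpr), from (0,0) to (1,1)
    n_test: int


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC; ties between classes count one half."""
    scores = np.asarray(scores, np.float64)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes in the test set")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> list[tuple[float, float]]:
    """ROC by sweeping the unique score thresholds, high to low."""
    scores = np.asarray(scores, np.float64)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    order = np.argsort(-scores, kind="mergesort")
    s, lab = scores[order], labels[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            tp += int(lab[j])
            fp += int(not lab[j])
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    return points


def evaluate_blind(
    model: ModelSpec,
    test: FeatureTable,
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> EvaluationReport:
    """Blind accuracy (with bootstrap percentile CI), rank AUC, and ROC."""
    positive = model.contrast[4:]
    overlap = set(model.train_ids) & set(test.data.index)
    if overlap:
        raise ValueError(f"test set overlaps training ids: {sorted(overlap)[:3]}...")
    y = (test.labels == positive).to_numpy(int)
    scores = model.scores(test.data).to_numpy()
    pred = (scores >= model.decision_threshold).astype(int)
    accuracy = float((pred == y).mean())
    auc = rank_auc(scores, y)
    rng = np.random.default_rng(seed)
    n = len(y)
    idx = rng.integers(0, n, size=(n_bootstrap, n))
    boot = (pred[idx] == y[idx]).mean(axis=1)
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    return EvaluationReport(
        accuracy=accuracy,
        accuracy_ci95=ci,
        auc=auc,
        roc=roc_points(scores, y),
        n_test=n,
    )


# ---------------------------------------------------------------------------
# side-swap sensitivity
# ---------------------------------------------------------------------------

def swap_side_features(vector: pd.Series) -> pd.Series:
    """Exchange every left/right per-image feature with its contralateral twin.

    Subtraction-image and symmetric (avg/absdiff) entries are untouched;
    applying the swap twice returns the original vector.
    """
    rename = {}
    for name in vector.index:
        m = _PER_IMAGE_RE.match(name)
        if m:
            view, variant, side, feat = m.groups()
            other = "l" if side == "r" else "r"
            rename[name] = f"{view}_{variant}_{other}_{feat}"
    swapped = vector.rename(rename)
    return swapped.reindex(vector.index)


def swap_side_table(data: pd.DataFrame) -> pd.DataFrame:
    """Column-wise :func:`swap_side_features` for a whole table."""
    rename = {}
    for name in data.columns:
        m = _PER_IMAGE_RE.match(name)
        if m:
            view, variant, side, feat = m.groups()
            other = "l" if side == "r" else "r"
            rename[name] = f"{view}_{variant}_{other}_{feat}"
    return data.rename(columns=rename).loc[:, data.columns]


# ---------------------------------------------------------------------------
# triage arithmetic
# ---------------------------------------------------------------------------

@dataclass
class ModelCutoffs:
    specificity_cutoff: float
    sensitivity_cutoff: float
    achieved_specificity: float
    achieved_sensitivity: float
    low_priority_fraction: float  # fraction of all calibration subjects cleared
    target_met: bool


@dataclass
class TriageReport:
    calc: ModelCutoffs
    mass: ModelCutoffs
    high_priority: np.ndarray  # flagged by either model at its specificity cutoff
    low_priority: np.ndarray  # cleared by both models at their sensitivity cutoffs
    observed_high_fraction: float
    observed_low_fraction: float
    expected_high_fraction: float  # 1 - spec1*spec2 under independence
    expected_low_fraction: float  # low1*low2 under independence


def independent_triage_fractions(
    spec1: float, spec2: float, low1: float, low2: float
) -> tuple[float, float]:
    """Independence-approximation high/low priority fractions.

    Two detectors at specificities spec1, spec2 flag 1 - spec1*spec2 of
    subjects into the high priority group; two low-priority rules clearing
    fractions low1, low2 jointly clear low1*low2.
    """
    return 1.0 - spec1 * spec2, low1 * low2


def _model_cutoffs(scores: np.ndarray, diseased: np.ndarray, sens_target: float, spec_target: float) -> ModelCutoffs:
    scores = np.asarray(scores, np.float64)
    diseased = np.asarray(diseased).astype(bool)
    healthy_scores = np.sort(scores[~diseased])
    diseased_scores = np.sort(scores[diseased])
    if healthy_scores.size == 0 or diseased_scores.size == 0:
        raise ValueError("triage calibration needs both classes")
    candidates = np.unique(scores)
    # specificity cutoff: smallest threshold keeping >= spec_target of
    # healthy below it (flag = score >= cutoff)
    spec_ok = [
        t for t in candidates if (healthy_scores < t).mean() >= spec_target
    ]
    spec_met = bool(spec_ok)
    spec_cut = float(min(spec_ok)) if spec_met else float(healthy_scores.max() + 1e-12)
    # sensitivity cutoff: largest threshold keeping >= sens_target of
    # diseased at or above it (clear = score < cutoff)
    sens_ok = [
        t for t in candidates if (diseased_scores >= t).mean() >= sens_target
    ]
    sens_met = bool(sens_ok)
    sens_cut = float(max(sens_ok)) if sens_met else float(diseased_scores.min())
    return ModelCutoffs(
        specificity_cutoff=spec_cut,
        sensitivity_cutoff=sens_cut,
        achieved_specificity=float((healthy_scores < spec_cut).mean()),
        achieved_sensitivity=float((diseased_scores >= sens_cut).mean()),
        low_priority_fraction=float((scores < sens_cut).mean()),
        target_met=spec_met and sens_met,
    )


def triage_groups(
    scores_calc: np.ndarray,
    diseased_calc: np.ndarray,
    scores_mass: np.ndarray,
    diseased_mass: np.ndarray,
    sens_target: float = 0.90,
    spec_target: float = 0.90,
) -> TriageReport:
    """Combine the two models' cutoffs into high/low priority reading groups.

    Both score lists must cover the same subjects in the same order (their
    disease indicators may differ: calcification vs mass ground truth).
    """
    scores_calc = np.asarray(scores_calc, np.float64)
    scores_mass = np.asarray(scores_mass, np.float64)
    if scores_calc.shape != scores_mass.shape:
        raise ValueError("the two score lists must cover the same subjects")
    calc = _model_cutoffs(scores_calc, diseased_calc, sens_target, spec_target)
    mass = _model_cutoffs(scores_mass, diseased_mass, sens_target, spec_target)
    high = (scores_calc >= calc.specificity_cutoff) | (scores_mass >= mass.specificity_cutoff)
    low = (scores_calc < calc.sensitivity_cutoff) & (scores_mass < mass.sensitivity_cutoff)
    expected_high, expected_low = independent_triage_fractions(
        calc.achieved_specificity,
        mass.achieved_specificity,
        calc.low_priority_fraction,
        mass.low_priority_fraction,
    )
    return TriageReport(
        calc=calc,
        mass=mass,
        high_priority=high,
        low_priority=low,
        observed_high_fraction=float(high.mean()),
        observed_low_fraction=float(low.mean()),
        expected_high_fraction=expected_high,
        expected_low_fraction=expected_low,
    )
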