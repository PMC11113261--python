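"""Linear aging clocks on cfDNA nucleosomics features.

Two feature kinds are supported, mirroring the two integral chromatin
summaries that carry age signal:

* ``size_dist`` — the fragment-size frequency vector over 100-600 bp
  (501 features; each row sums to 1);
* ``distance_autocorr`` — the smoothed, normalised phasogram over the fit
  range (120-2000 bp by default).

With hundreds of correlated features and cohorts of tens of samples a raw
multiple linear regression is underdetermined, so the default clock is
principal-component regression: standardise on the training split, project
onto the top-k training principal components, and fit OLS on the component
scores — a linear model in the original features.  Ridge regression on the
standardised features is available as an alternative mode.  Evaluation uses
a seeded 80/20 split stratified by age tertile; the test rows never touch
standardisation, loadings or coefficients.

The same clock also serves as an age-group classifier: the predicted age is
the ROC score for the (age > threshold) label, with AUC computed by the
rank (Mann-Whitney) formula with tie correction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression, LogisticRegression, Ridge

from .fragmentomics import size_distribution
from .io_fragments import FragmentSet, SampleMeta
from .phasogram_nrl import (
    D_MAX_DEFAULT,
    D_MIN_FIT_DEFAULT,
    SG_POLYORDER_DEFAULT,
    SG_WINDOW_DEFAULT,
    compute_phasogram,
    smooth_phasogram,
)

__all__ = [
    "FeatureMatrix",
    "ClockModel",
    "ClockMetrics",
    "build_features",
    "train_clock",
    "predict_age",
    "classify_age_group",
    "evaluate_metrics",
    "auc_mann_whitney",
    "stratified_split",
]

FEATURE_KINDS = ("size_dist", "distance_autocorr")


@dataclass
class FeatureMatrix:
    """Samples-by-features matrix for one feature kind."""

    sample_ids: list[str]
    feature_kind: str
    X: np.ndarray          # (n_samples, n_features)
    grid: np.ndarray       # feature coordinate (bp) per column
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"feature_kind must be one of {FEATURE_KINDS}")
        if self.X.shape != (len(self.sample_ids), len(self.grid)):
            raise ValueError("matrix shape must be (n_samples, n_features)")
        if np.any(~np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


def build_features(
    samples: list[tuple[FragmentSet, SampleMeta]],
    feature_kind: str,
    size_range: tuple[int, int] = (100, 600),
    d_max: int = D_MAX_DEFAULT,
    d_min_fit: int = D_MIN_FIT_DEFAULT,
    sg_window: int = SG_WINDOW_DEFAULT,
    sg_polyorder: int = SG_POLYORDER_DEFAULT,
) -> FeatureMatrix:
    """Compute the feature matrix for a cohort.

    ``size_dist`` rows are fragment-size frequencies over ``size_range``
    (rows sum to 1); ``distance_autocorr`` rows are the Savitzky-Golay
    smoothed normalised phasogram restricted to [d_min_fit, d_max].  Samples
    with an empty distribution are excluded with a warning and listed in
    ``FeatureMatrix.excluded``.
    """
    if feature_kind not in FEATURE_KINDS:
        raise ValueError(f"feature_kind must be one of {FEATURE_KINDS}")
    ids, rows, excluded = [], [], []
    for fs, meta in samples:
        if fs.n_fragments == 0:
            excluded.append(meta.sample_id)
            continue
        if feature_kind == "size_dist":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dist = size_distribution(fs, *size_range)
            if dist.is_empty:
                excluded.append(meta.sample_id)
                continue
            rows.append(dist.freq)
        else:
            p = compute_phasogram(fs, d_max=d_max)
            if p.n_pairs == 0:
                excluded.append(meta.sample_id)
                continue
            p = smooth_phasogram(p, window=sg_window, polyorder=sg_polyorder)
            rows.append(p.smoothed[d_min_fit:])
        ids.append(meta.sample_id)
    if excluded:
        warnings.warn(f"excluded {len(excluded)} sample(s) with empty features: {excluded}")
    if not rows:
        raise ValueError("no usable samples")
    grid = (
        np.arange(size_range[0], size_range[1] + 1)
        if feature_kind == "size_dist"
        else np.arange(d_min_fit, d_max + 1)
    )
    return FeatureMatrix(
        sample_ids=ids, feature_kind=feature_kind, X=np.vstack(rows), grid=grid,
        excluded=excluded,
    )


@dataclass
class ClockMetrics:
    """Predicted-vs-chronological agreement on a held-out split."""

    pearson_r: float
    mse: float                 # years^2
    median_abs_error: float    # years
    auc: float | None = None
    flagged: bool = False      # r undefined (zero-variance predictions)


@dataclass
class ClockModel:
    """A fitted linear age predictor.

    Prediction: standardise features with the training means/SDs, project
    onto the stored loadings (PCR mode) or use them directly (ridge mode),
    then apply the linear coefficients and intercept.
    """

    feature_kind: str
    grid: np.ndarray
    feature_means: np.ndarray
    feature_sds: np.ndarray
    loadings: np.ndarray | None    # (k, n_features) PCs; None in ridge mode
    coef: np.ndarray
    intercept: float
    mode: str = "pcr"
    k: int | None = 10
    seed: int = 0
    split_fraction: float = 0.8
    train_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        d = {
            "feature_kind": self.feature_kind,
            "grid": self.grid.tolist(),
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "loadings": None if self.loadings is None else self.loadings.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "mode": self.mode,
            "k": self.k,
            "seed": self.seed,
            "split_fraction": self.split_fraction,
            "train_ids": self.train_ids,
            "test_ids": self.test_ids,
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClockModel":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_kind=d["feature_kind"],
            grid=np.array(d["grid"]),
            feature_means=np.array(d["feature_means"]),
            feature_sds=np.array(d["feature_sds"]),
            loadings=None if d["loadings"] is None else np.array(d["loadings"]),
            coef=np.array(d["coef"]),
            intercept=float(d["intercept"]),
            mode=d["mode"],
            k=d["k"],
            seed=d["seed"],
            split_fraction=d["split_fraction"],
            train_ids=d["train_ids"],
            test_ids=d["test_ids"],
        )


def stratified_split(
    ages: np.ndarray, split_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random train/test partition stratified by age tertile.

    Within each tertile a seeded shuffle sends ~(1 - split_fraction) of the
    samples to the test set, so the test ages span the cohort's range even at
    small n.  Returns (train_idx, test_idx).
    """
    ages = np.asarray(ages, dtype=float)
    n = len(ages)
    rng = np.random.default_rng(seed)
    order = np.argsort(ages, kind="stable")
    tertiles = np.array_split(order, 3)
    train, test = [], []
    for tert in tertiles:
        tert = rng.permutation(tert)
        n_test = int(round(len(tert) * (1 - split_fraction)))
        test.extend(tert[:n_test])
        train.extend(tert[n_test:])
    train_idx = np.sort(np.array(train, dtype=int))
    test_idx = np.sort(np.array(test, dtype=int))
    if len(test_idx) < 2:
        raise ValueError("degenerate test split (n_test < 2); lower split_fraction")
    return train_idx, test_idx


def _standardise(X: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    sds = np.where(sds > 0, sds, 1.0)
    return (X - means) / sds


def train_clock(
    features: FeatureMatrix,
    ages: np.ndarray,
    split_fraction: float = 0.8,
    k: int = 10,
    seed: int = 0,
    mode: str = "pcr",
    ridge_alpha: float = 1.0,
) -> tuple[ClockModel, ClockMetrics]:
    """Fit the clock on a stratified train split; score the untouched test split.

    Standardisation, loadings and coefficients come from the training rows
    only.  ``mode='pcr'`` (default) regresses age on the top-``k`` training
    principal components; ``mode='ridge'`` fits ridge regression on the
    standardised features directly.
    """
    ages = np.asarray(ages, dtype=float)
    if features.n_samples != len(ages):
        raise ValueError("ages must match feature rows")
    if features.n_samples < 10:
        raise ValueError("need at least 10 samples")
    if not np.all(np.isfinite(ages)):
        raise ValueError("ages must be finite")
    train_idx, test_idx = stratified_split(ages, split_fraction, seed)
    X_train, y_train = features.X[train_idx], ages[train_idx]
    X_test, y_test = features.X[test_idx], ages[test_idx]

    means = X_train.mean(axis=0)
    sds = X_train.std(axis=0, ddof=0)
    Z_train = _standardise(X_train, means, sds)

    if mode == "pcr":
        if k >= len(train_idx) - 1:
            raise ValueError("k must be <= n_train - 2")
        pca = PCA(n_components=k, svd_solver="full")
        # PCA re-centres; Z_train columns already have mean 0, so loadings
        # apply directly to standardised features at prediction time.
        T_train = pca.fit_transform(Z_train)
        reg = LinearRegression().fit(T_train, y_train)
        loadings = pca.components_
        coef = reg.coef_
        intercept = float(reg.intercept_)
    elif mode == "ridge":
        reg = Ridge(alpha=ridge_alpha).fit(Z_train, y_train)
        loadings = None
        coef = reg.coef_
        intercept = float(reg.intercept_)
    else:
        raise ValueError("mode must be 'pcr' or 'ridge'")

    model = ClockModel(
        feature_kind=features.feature_kind,
        grid=features.grid.copy(),
        feature_means=means,
        feature_sds=sds,
        loadings=loadings,
        coef=coef,
        intercept=intercept,
        mode=mode,
        k=k if mode == "pcr" else None,
        seed=seed,
        split_fraction=split_fraction,
        train_ids=[features.sample_ids[i] for i in train_idx],
        test_ids=[features.sample_ids[i] for i in test_idx],
    )
    pred_test = predict_age(model, X_test)
    metrics = evaluate_metrics(pred_test, y_test)
    return model, metrics


def predict_age(model: ClockModel, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Predicted ages (years) for feature rows on the model's grid."""
    if isinstance(features, FeatureMatrix):
        if features.feature_kind != model.feature_kind or not np.array_equal(
            features.grid, model.grid
        ):
            raise ValueError("feature grid does not match model")
        X = features.X
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[1] != len(model.grid):
            raise ValueError(
                f"expected {len(model.grid)} features, got {X.shape[1]}"
            )
    Z = _standardise(X, model.feature_means, model.feature_sds)
    T = Z @ model.loadings.T if model.loadings is not None else Z
    return T @ model.coef + model.intercept


def evaluate_metrics(predicted: np.ndarray, chronological: np.ndarray) -> ClockMetrics:
    """Pearson r, MSE and median absolute error of predictions."""
    predicted = np.asarray(predicted, dtype=float)
    chronological = np.asarray(chronological, dtype=float)
    if predicted.shape != chronological.shape or predicted.ndim != 1:
        raise ValueError("predicted and chronological must be equal-length vectors")
    if len(predicted) < 2:
        raise ValueError("need at least 2 samples")
    resid = predicted - chronological
    mse = float(np.mean(resid**2))
    medae = float(np.median(np.abs(resid)))
    if np.std(predicted) == 0 or np.std(chronological) == 0:
        return ClockMetrics(pearson_r=np.nan, mse=mse, median_abs_error=medae, flagged=True)
    r, _ = stats.pearsonr(predicted, chronological)
    return ClockMetrics(pearson_r=float(r), mse=mse, median_abs_error=medae)


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney U) formula with average-rank tie correction."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)  # average ranks handle ties
    r1 = ranks[labels].sum()
    u1 = r1 - n1 * (n1 + 1) / 2
    return float(u1 / (n1 * n0))


def classify_age_group(
    scores_or_features,
    ages: np.ndarray,
    threshold_years: float = 55.0,
    mode: str = "clock",
    split_fraction: float = 0.8,
    k: int = 10,
    seed: int = 0,
) -> float:
    """AUC for separating subjects (age > threshold) from the rest.

    ``mode='clock'``: ``scores_or_features`` is a score vector (typically the
    clock's predicted ages on a test split) and AUC is computed directly.
    ``mode='logistic'``: ``scores_or_features`` is a FeatureMatrix; a
    standardise + PCA + logistic-regression pipeline is fitted on a stratified
    training split and AUC is reported on the held-out split.
    """
    ages = np.asarray(ages, dtype=float)
    labels = ages > threshold_years
    if mode == "clock":
        scores = np.asarray(scores_or_features, dtype=float)
        if scores.shape != ages.shape:
            raise ValueError("scores and ages must have equal length")
        return auc_mann_whitney(scores, labels)
    if mode != "logistic":
        raise ValueError("mode must be 'clock' or 'logistic'")
    features: FeatureMatrix = scores_or_features
    train_idx, test_idx = stratified_split(ages, split_fraction, seed)
    if labels[test_idx].all() or not labels[test_idx].any():
        raise ValueError("single-class test set; adjust threshold or split")
    means = features.X[train_idx].mean(axis=0)
    sds = features.X[train_idx].std(axis=0, ddof=0)
    Z_train = _standardise(features.X[train_idx], means, sds)
    Z_test = _standardise(features.X[test_idx], means, sds)
    k_eff = min(k, len(train_idx) - 2)
    pca = PCA(n_components=k_eff, svd_solver="full")
    T_train = pca.fit_transform(Z_train)
    T_test = (Z_test - pca.mean_) @ pca.components_.T
    clf = LogisticRegression(max_iter=1000).fit(T_train, labels[train_idx])
    scores = clf.decision_function(T_test)
    return auc_mann_whitney(scores, labels[test_idx])
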