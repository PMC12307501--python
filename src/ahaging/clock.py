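"""Proteomic age clock.

The signature is chosen by stability selection: a LASSO fit (lambda at the
10-fold cross-validation minimum) is repeated with fresh random CV
partitions, and features retained in more than half the repetitions form the
signature. A ridge regression of age on the standardized signature proteins
plus sex produces raw predictions; a calibration regression of predicted on
chronological age over the training samples removes regression-to-the-mean
bias ("unbiased age" = (predicted - intercept)/slope). Δage = unbiased minus
chronological age feeds MAE, ager classification (decelerated / accelerated /
chronological), per-protein AUC and random-signature null comparisons.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .core_data import AbundanceTable, CohortMetadata, GROUP_OLDER, GROUP_YOUNG
from .errors import ConfigurationError, ValidationError

__all__ = [
    "ClockConfig",
    "ClockModel",
    "ClockResult",
    "split_train_test",
    "lasso_stability_selection",
    "ridge_fit",
    "fit_ridge_clock",
    "predict_age",
    "calibrate_unbiased",
    "compute_delta_age_and_mae",
    "classify_agers",
    "protein_auc",
    "random_signature_null",
    "fit_aging_clock",
]


@dataclass(frozen=True)
class ClockConfig:
    """Clock hyperparameters.

    n_train (default 33) training samples are drawn at random; LASSO is
    repeated n_reps times with cv_folds-fold CV; signature features must be
    retained strictly more than freq_threshold times (default n_reps/2).
    Ager thresholds: decelerated Δage <= da_threshold, accelerated
    Δage >= aa_threshold, chronological |Δage| < ca_band.
    """

    n_train: int = 33
    n_reps: int = 1000
    cv_folds: int = 10
    freq_threshold: float | None = None
    ridge_lambda: float | None = None
    ridge_lambdas: tuple[float, ...] | None = None
    lasso_grid_size: int = 100
    lasso_grid_decades: float = 4.0
    da_threshold: float = -5.0
    aa_threshold: float = 5.0
    ca_band: float = 2.0
    bootstrap: bool = False
    calibrate_on: str = "train"
    seed: int = 0

    def __post_init__(self):
        if self.n_train <= 0:
            raise ConfigurationError("n_train must be positive")
        if self.n_reps < 1:
            raise ConfigurationError("n_reps must be >= 1")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")
        if not (self.da_threshold < 0 < self.aa_threshold):
            raise ConfigurationError("need da_threshold < 0 < aa_threshold")
        if self.ca_band <= 0:
            raise ConfigurationError("ca_band must be positive")
        if self.calibrate_on not in ("train", "all"):
            raise ConfigurationError("calibrate_on must be 'train' or 'all'")

    @property
    def effective_freq_threshold(self) -> float:
        return self.n_reps / 2 if self.freq_threshold is None else self.freq_threshold

    def ridge_grid(self) -> np.ndarray:
        if self.ridge_lambdas is not None:
            return np.asarray(self.ridge_lambdas, dtype=float)
        return np.logspace(-3, 5, 100)


@dataclass
class ClockModel:
    """A fitted ridge clock plus its calibration line.

    Coefficients live on the standardized-feature scale; feature_means and
    feature_sds are the training-set standardization parameters (sex is kept
    on its 0/1 coding with mean 0 / sd 1 stored). calibration_intercept and
    calibration_slope come from the linear model predicted ~ chronological.
    """

    features: list[str]
    coefficients: pd.Series
    intercept: float
    ridge_lambda: float
    feature_means: pd.Series
    feature_sds: pd.Series
    signature: list[str] = field(default_factory=list)
    frequencies: pd.Series | None = None
    calibration_intercept: float | None = None
    calibration_slope: float | None = None

    def to_json(self, path) -> None:
        payload = {
            "features": self.features,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "intercept": float(self.intercept),
            "ridge_lambda": float(self.ridge_lambda),
            "feature_means": {k: float(v) for k, v in self.feature_means.items()},
            "feature_sds": {k: float(v) for k, v in self.feature_sds.items()},
            "signature": self.signature,
            "frequencies": (None if self.frequencies is None
                            else {k: int(v) for k, v in self.frequencies.items()}),
            "calibration_intercept": self.calibration_intercept,
            "calibration_slope": self.calibration_slope,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ClockModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            features=d["features"],
            coefficients=pd.Series(d["coefficients"]),
            intercept=d["intercept"],
            ridge_lambda=d["ridge_lambda"],
            feature_means=pd.Series(d["feature_means"]),
            feature_sds=pd.Series(d["feature_sds"]),
            signature=d["signature"],
            frequencies=None if d["frequencies"] is None else pd.Series(d["frequencies"]),
            calibration_intercept=d["calibration_intercept"],
            calibration_slope=d["calibration_slope"],
        )


def split_train_test(meta: CohortMetadata, cfg: ClockConfig) -> tuple[list[str], list[str]]:
    """Uniform random split without replacement, reproducible from cfg.seed."""
    ids = np.asarray(meta.sample_ids)
    if cfg.n_train >= len(ids):
        raise ValidationError(f"n_train={cfg.n_train} must be < cohort size {len(ids)}")
    rng = np.random.default_rng(cfg.seed)
    train = rng.choice(ids, size=cfg.n_train, replace=False)
    train_set = set(train)
    test = [s for s in ids if s not in train_set]
    return list(train), test


def lasso_stability_selection(
    X: pd.DataFrame,
    y: pd.Series,
    cfg: ClockConfig,
) -> tuple[pd.Series, list[str]]:
    """Repeated LASSO at the CV-minimum lambda; count feature retention.

    ``X`` holds training samples (rows) by candidate features (columns);
    features are standardized within the training set. Each repetition draws
    a fresh random cv_folds partition (optionally a bootstrap resample),
    picks lambda minimizing CV mean-squared error on a descending log-spaced
    grid from lambda_max over ``lasso_grid_decades`` decades, refits, and
    records the nonzero set. Signature = features retained strictly more than
    the frequency threshold.
    """
    n, p = X.shape
    if n < cfg.cv_folds:
        raise ValidationError(f"need >= {cfg.cv_folds} training samples for CV")
    y_arr = np.asarray(y, dtype=float)
    values = X.to_numpy(dtype=float)
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = list(X.columns[sds == 0])
        raise ValidationError(f"zero-variance candidate features: {bad}")
    Xs = (values - means) / sds
    lam_max = np.max(np.abs(Xs.T @ (y_arr - y_arr.mean()))) / n
    alphas = np.geomspace(lam_max, lam_max * 10 ** (-cfg.lasso_grid_decades),
                          cfg.lasso_grid_size)
    rng = np.random.default_rng(cfg.seed)
    rep_states = rng.integers(0, 2**31 - 1, size=cfg.n_reps)
    counts = np.zeros(p, dtype=int)
    for rep_state in rep_states:
        rep_rng = np.random.default_rng(int(rep_state))
        if cfg.bootstrap:
            rows = rep_rng.integers(0, n, size=n)
            X_rep, y_rep = Xs[rows], y_arr[rows]
        else:
            X_rep, y_rep = Xs, y_arr
        kf = KFold(n_splits=cfg.cv_folds, shuffle=True,
                   random_state=int(rep_rng.integers(0, 2**31 - 1)))
        model = LassoCV(alphas=alphas, cv=kf, max_iter=20000, tol=1e-4)
        model.fit(X_rep, y_rep)
        counts += model.coef_ != 0
    frequencies = pd.Series(counts, index=X.columns, name="frequency")
    threshold = cfg.effective_freq_threshold
    signature = list(frequencies.index[frequencies > threshold])
    return frequencies, signature


def ridge_fit(X: np.ndarray, y: np.ndarray, lam: float, fit_intercept: bool = True):
    """Closed-form ridge: beta = (X'X + lam I)^-1 X'y, intercept unpenalized.

    With ``fit_intercept`` the columns of X and y are centred first, so the
    intercept absorbs the means. lam = 0 reduces to (minimum-norm) OLS.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if fit_intercept:
        x_mean = X.mean(axis=0)
        y_mean = y.mean()
        Xc, yc = X - x_mean, y - y_mean
    else:
        x_mean = np.zeros(X.shape[1])
        y_mean = 0.0
        Xc, yc = X, y
    p = X.shape[1]
    gram = Xc.T @ Xc + lam * np.eye(p)
    try:
        beta = np.linalg.solve(gram, Xc.T @ yc)
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    intercept = y_mean - x_mean @ beta if fit_intercept else 0.0
    return beta, float(intercept)


def _ridge_cv_lambda(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
                     folds: int, seed: int) -> float:
    """Grid search: lambda minimizing K-fold CV mean squared error."""
    n = X.shape[0]
    folds = min(folds, n)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed % (2**31 - 1))
    errors = np.zeros(lambdas.size)
    for train_idx, test_idx in kf.split(X):
        for i, lam in enumerate(lambdas):
            beta, intercept = ridge_fit(X[train_idx], y[train_idx], lam)
            pred = X[test_idx] @ beta + intercept
            errors[i] += float(np.sum((pred - y[test_idx]) ** 2))
    return float(lambdas[int(np.argmin(errors))])


def _feature_matrix(table: AbundanceTable, meta: CohortMetadata,
                    proteins: Sequence[str], sample_ids: Sequence[str]) -> pd.DataFrame:
    missing = [p for p in proteins if p not in table.data.index]
    if missing:
        raise ValidationError(f"signature proteins missing from table: {missing}")
    mat = table.data.loc[list(proteins), list(sample_ids)].T
    mat["sex"] = meta.sex.loc[list(sample_ids)].to_numpy(dtype=float)
    return mat


def fit_ridge_clock(
    table: AbundanceTable,
    meta: CohortMetadata,
    signature: Sequence[str],
    cfg: ClockConfig,
    train_ids: Sequence[str],
) -> ClockModel:
    """Ridge regression of age on standardized signature proteins plus sex.

    Lambda is fixed by cfg.ridge_lambda or chosen at the CV minimum on the
    training set; coefficients are stored on the standardized scale together
    with the training-set standardization parameters.
    """
    signature = list(signature)
    if not signature:
        raise ValidationError(
            "empty signature: relax the stability-selection frequency threshold"
        )
    meta.check_matches(table)
    feats = _feature_matrix(table, meta, signature, train_ids)
    y = meta.age.loc[list(train_ids)].to_numpy(dtype=float)
    means = feats.mean(axis=0)
    sds = feats.std(axis=0, ddof=1)
    means["sex"], sds["sex"] = 0.0, 1.0  # sex stays on its 0/1 coding
    sds = sds.where(sds > 0, 1.0)
    Xs = ((feats - means) / sds).to_numpy(dtype=float)
    if cfg.ridge_lambda is not None:
        lam = float(cfg.ridge_lambda)
    else:
        lam = _ridge_cv_lambda(Xs, y, cfg.ridge_grid(), cfg.cv_folds, cfg.seed)
    beta, intercept = ridge_fit(Xs, y, lam)
    return ClockModel(
        features=list(feats.columns),
        coefficients=pd.Series(beta, index=feats.columns, name="coefficient"),
        intercept=intercept,
        ridge_lambda=lam,
        feature_means=means,
        feature_sds=sds,
        signature=signature,
    )


def predict_age(model: ClockModel, table: AbundanceTable, meta: CohortMetadata) -> pd.Series:
    """Apply the stored standardization and linear model; returns years."""
    proteins = [f for f in model.features if f != "sex"]
    feats = _feature_matrix(table, meta, proteins, table.sample_ids)
    feats = feats[model.features]
    Xs = ((feats - model.feature_means) / model.feature_sds).to_numpy(dtype=float)
    pred = Xs @ model.coefficients.to_numpy(dtype=float) + model.intercept
    return pd.Series(pred, index=table.sample_ids, name="predicted_age")


def calibrate_unbiased(
    predicted: pd.Series,
    chronological: pd.Series,
    fit_on: Iterable[str],
) -> tuple[float, float, pd.Series]:
    """Bias correction through the calibration line.

    OLS of predicted on chronological age over ``fit_on``; unbiased age =
    (predicted - intercept)/slope applied to every sample. By construction
    the mean Δage over ``fit_on`` is zero.
    """
    fit_ids = list(fit_on)
    if len(fit_ids) < 3:
        raise ValidationError("need at least 3 calibration samples")
    c = chronological.loc[fit_ids].to_numpy(dtype=float)
    p = predicted.loc[fit_ids].to_numpy(dtype=float)
    if np.ptp(c) == 0:
        raise ValidationError("calibration requires age variance")
    slope, intercept = np.polyfit(c, p, 1)
    if abs(slope) < 1e-8:
        raise ValidationError("degenerate clock: calibration slope ~ 0")
    unbiased = (predicted - intercept) / slope
    unbiased.name = "unbiased_age"
    return float(intercept), float(slope), unbiased


def compute_delta_age_and_mae(
    unbiased: pd.Series,
    chronological: pd.Series,
) -> tuple[pd.Series, float]:
    """Δage = unbiased - chronological (years); MAE = mean |Δage|."""
    if len(unbiased) == 0:
        raise ValidationError("empty input")
    if len(unbiased) != len(chronological):
        raise ValidationError("inputs must have equal length")
    delta = unbiased - chronological.loc[unbiased.index]
    delta.name = "delta_age"
    return delta, float(delta.abs().mean())


def classify_agers(delta_age: pd.Series, cfg: ClockConfig | None = None) -> pd.Series:
    """Map Δage to DA (<= -5), AA (>= +5), CA (|Δage| < 2) or unclassified."""
    cfg = cfg or ClockConfig()
    d = delta_age.to_numpy(dtype=float)
    out = np.full(d.shape, "unclassified", dtype=object)
    out[np.abs(d) < cfg.ca_band] = "CA"
    out[d <= cfg.da_threshold] = "DA"
    out[d >= cfg.aa_threshold] = "AA"
    return pd.Series(out, index=delta_age.index, name="ager_class")


def protein_auc(expr: pd.Series, groups: pd.Series) -> float:
    """Mann-Whitney AUC: P(older value > young value), ties counted half.

    Orientation is fixed as older-vs-young (never flipped), so an AUC below
    0.5 indicates lower abundance in the older group.
    """
    groups = groups.loc[expr.index]
    older = expr[groups == GROUP_OLDER].to_numpy(dtype=float)
    young = expr[groups == GROUP_YOUNG].to_numpy(dtype=float)
    if older.size == 0 or young.size == 0:
        raise ValidationError("both groups must be non-empty")
    greater = (older[:, None] > young[None, :]).sum()
    ties = (older[:, None] == young[None, :]).sum()
    return float((greater + 0.5 * ties) / (older.size * young.size))


def random_signature_null(
    table: AbundanceTable,
    meta: CohortMetadata,
    size: int,
    n_draws: int,
    cfg: ClockConfig,
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    exclude: Iterable[str] = (),
) -> np.ndarray:
    """Test-set Pearson r distribution for clocks built on random protein sets."""
    eligible = [p for p in table.protein_ids if p not in set(exclude)]
    if size > len(eligible):
        raise ValidationError("size exceeds the number of eligible proteins")
    rng = np.random.default_rng(cfg.seed)
    ages_test = meta.age.loc[list(test_ids)].to_numpy(dtype=float)
    rs = np.empty(n_draws)
    for i in range(n_draws):
        draw = list(rng.choice(eligible, size=size, replace=False))
        model = fit_ridge_clock(table, meta, draw, cfg, train_ids)
        pred = predict_age(model, table.subset_samples(test_ids), meta)
        rs[i] = sps.pearsonr(pred.to_numpy(), ages_test)[0]
    return rs


@dataclass
class ClockResult:
    """End-to-end clock outputs for one cohort."""

    signature_model: ClockModel
    full_model: ClockModel
    frequencies: pd.Series
    assessments: pd.DataFrame
    train_ids: list[str]
    test_ids: list[str]
    mae_train: float
    mae_test: float
    test_r: float


def fit_aging_clock(
    table: AbundanceTable,
    meta: CohortMetadata,
    ap_ids: Sequence[str],
    cfg: ClockConfig,
) -> ClockResult:
    """Full clock workflow on an imputed table restricted to aging proteins.

    Splits the cohort, runs stability selection over the APs on the training
    samples, fits the reduced-signature ridge clock and a full-AP ridge
    clock, calibrates on the training set (or all samples per
    cfg.calibrate_on), and assembles per-sample age assessments. The Δage
    used for ager classification comes from the full-AP model.
    """
    meta.check_matches(table)
    ap_ids = list(ap_ids)
    train_ids, test_ids = split_train_test(meta, cfg)
    X_train = table.data.loc[ap_ids, train_ids].T
    y_train = meta.age.loc[train_ids]
    frequencies, signature = lasso_stability_selection(X_train, y_train, cfg)
    signature_model = fit_ridge_clock(table, meta, signature, cfg, train_ids)
    full_model = fit_ridge_clock(table, meta, ap_ids, cfg, train_ids)

    predicted = predict_age(full_model, table, meta)
    fit_on = train_ids if cfg.calibrate_on == "train" else table.sample_ids
    intercept, slope, unbiased = calibrate_unbiased(predicted, meta.age, fit_on)
    full_model.calibration_intercept = intercept
    full_model.calibration_slope = slope
    delta, _ = compute_delta_age_and_mae(unbiased, meta.age)
    classes = classify_agers(delta, cfg)

    pred_sig = predict_age(signature_model, table, meta)
    sig_int, sig_slope, sig_unbiased = calibrate_unbiased(pred_sig, meta.age, fit_on)
    signature_model.calibration_intercept = sig_int
    signature_model.calibration_slope = sig_slope
    signature_model.frequencies = frequencies

    mae_train = float((delta.loc[train_ids]).abs().mean())
    mae_test = float((delta.loc[test_ids]).abs().mean())
    test_r = float(sps.pearsonr(
        sig_unbiased.loc[test_ids].to_numpy(),
        meta.age.loc[test_ids].to_numpy(),
    )[0])
    assessments = pd.DataFrame({
        "predicted_age": predicted,
        "unbiased_age": unbiased,
        "delta_age": delta,
        "ager_class": classes,
        "split": ["train" if s in set(train_ids) else "test" for s in table.sample_ids],
    })
    assessments.index.name = "sample_id"
    return ClockResult(
        signature_model=signature_model,
        full_model=full_model,
        frequencies=frequencies,
        assessments=assessments,
        train_ids=train_ids,
        test_ids=test_ids,
        mae_train=mae_train,
        mae_test=mae_test,
        test_r=test_r,
    )
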