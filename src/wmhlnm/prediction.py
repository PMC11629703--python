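"""Ridge-regression benchmark of cognitive prediction from lesion features.

Six feature sets — demographics alone, plus total lesion volume, tract-level
lesion volumes, fLNM scores, sLNM scores, or both LNM modalities — are
compared per cognitive domain under repeated nested cross-validation
(outer 10-fold x 10 repeats; inner loop tunes the L2 penalty on the grid
alpha in {0.001, 0.01, 0.1, 1, 10, 100, 1000}). Folds stratify the
continuous target via quantile bins. Continuous features are z-scored with
training-fold statistics only; binary sex is left unscaled. Performance is
the Pearson correlation between actual and predicted scores, supplemented
by sum-of-squares R^2 and negative MSE. Feature sets are compared with the
corrected resampled (paired) t-test, whose variance is inflated by
n_test/n_train to account for overlapping training sets across folds.

Ridge solutions are computed exactly via an SVD of the (centred,
standardized) training matrix, which yields the whole alpha path from one
decomposition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

ALPHA_GRID = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)

FEATURE_SETS = (
    "demo",
    "demo+totalWMH",
    "demo+tractWMH",
    "demo+fLNM",
    "demo+sLNM",
    "demo+fLNM+sLNM",
)

DEMO_COLUMNS = ("age", "sex", "education")


@dataclass
class FeatureSet:
    """Design matrix for one feature set; ``continuous`` marks columns that
    are z-scored inside the CV (binary sex is not)."""

    id: str
    X: pd.DataFrame
    y: pd.Series
    continuous: np.ndarray  # bool per column

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class CVResult:
    """Per-(repeat, fold) test scores for one feature set and domain."""

    records: pd.DataFrame  # repeat, fold, pearson_r, r2_ss, neg_mse, alpha, n_train, n_test
    feature_set: str | None = None
    domain: str | None = None

    @property
    def mean_pearson_r(self) -> float:
        return float(np.nanmean(self.records["pearson_r"]))

    @property
    def scores(self) -> np.ndarray:
        return self.records["pearson_r"].to_numpy(float)


@dataclass
class ModelComparison:
    """Corrected resampled t-test between two feature sets' CV scores."""

    set_a: str
    set_b: str
    t: float
    p: float
    mean_diff: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# feature assembly


def assemble_features(
    set_id: str,
    patients: pd.DataFrame,
    domain: str,
    flnm=None,
    slnm=None,
    volumetrics=None,
) -> FeatureSet:
    """Build the design matrix for one feature set and domain.

    Patients with a missing target for the chosen domain are dropped before
    assembly (per-domain complete-case); features are never imputed.
    """
    if set_id not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {set_id!r}")
    if domain not in patients.columns:
        raise KeyError(f"domain {domain!r} not in patient table")
    tab = patients.reset_index(drop=True)
    keep = tab[domain].notna().to_numpy()
    tab = tab[keep]
    rows = tab.index.to_numpy()

    blocks = [tab[list(DEMO_COLUMNS)].astype(float)]
    cont = [True, False, True]  # age, sex, education

    def _need(obj, name):
        if obj is None:
            raise ValueError(f"feature set {set_id!r} requires {name}")
        return obj

    if set_id == "demo+totalWMH":
        vol = _need(volumetrics, "volumetric features")
        blocks.append(vol.total_wmh_ml.iloc[rows].to_frame().set_index(tab.index))
        cont += [True]
    elif set_id == "demo+tractWMH":
        vol = _need(volumetrics, "volumetric features")
        tract = vol.tract_wmh_ml.iloc[rows].set_index(tab.index)
        tract.columns = [f"tract_{c}_wmh_ml" for c in tract.columns]
        blocks.append(tract)
        cont += [True] * tract.shape[1]
    elif set_id in ("demo+fLNM", "demo+fLNM+sLNM"):
        mat = _need(flnm, "fLNM scores").scores.iloc[rows].set_index(tab.index)
        mat.columns = [f"flnm_{c}" for c in mat.columns]
        blocks.append(mat)
        cont += [True] * mat.shape[1]
    if set_id in ("demo+sLNM", "demo+fLNM+sLNM"):
        mat = _need(slnm, "sLNM scores").scores.iloc[rows].set_index(tab.index)
        mat.columns = [f"slnm_{c}" for c in mat.columns]
        blocks.append(mat)
        cont += [True] * mat.shape[1]

    X = pd.concat(blocks, axis=1)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing feature values after patient filtering: {bad[:5]}")
    return FeatureSet(set_id, X, tab[domain].astype(float), np.array(cont))


# ---------------------------------------------------------------------------
# folds


def continuous_stratified_folds(
    y: np.ndarray, k: int, n_bins: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold on quantile bins of a continuous target."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("more folds than samples")
    bins = min(n_bins, max(1, n // k))
    quantiles = np.quantile(y, np.linspace(0, 1, bins + 1)[1:-1])
    labels = np.searchsorted(quantiles, y, side="right")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**32 - 1))
    return [(tr, te) for tr, te in skf.split(np.zeros(n), labels)]


# ---------------------------------------------------------------------------
# scoring


def score_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Pearson r, sum-of-squares R^2 (can be negative) and negative MSE."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.size != y_pred.size or y_true.size < 3:
        raise ValueError("need equal-length arrays with n >= 3")
    resid = y_true - y_pred
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else float("nan")
    mse = float((resid**2).mean())
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(y_true, y_pred)[0, 1])
    return {"pearson_r": r, "r2_ss": r2, "neg_mse": -mse}


# ---------------------------------------------------------------------------
# ridge internals


def _standardize_train_test(X_tr, X_te, continuous):
    mu = X_tr.mean(axis=0)
    sd = np.where(continuous, X_tr.std(axis=0, ddof=0), 1.0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X_tr - mu) / sd, (X_te - mu) / sd


def _ridge_path(X_tr, y_tr, X_te, alphas):
    """Exact ridge predictions on X_te for every alpha, from one SVD.

    Columns are centred (intercept unpenalized); callers standardize first.
    """
    xm = X_tr.mean(axis=0)
    ym = y_tr.mean()
    Xc = X_tr - xm
    yc = y_tr - ym
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    Uty = U.T @ yc
    Xtc = X_te - xm
    XtV = Xtc @ Vt.T
    preds = []
    for a in alphas:
        shrink = s / (s**2 + a)
        preds.append(XtV @ (shrink * Uty) + ym)
    return preds


def nested_ridge_cv(
    X,
    y,
    k_outer: int = 10,
    k_inner: int = 5,
    alphas: Sequence[float] = ALPHA_GRID,
    repeats: int = 10,
    seed: int = 0,
    continuous: np.ndarray | None = None,
    n_bins: int = 10,
    feature_set: str | None = None,
    domain: str | None = None,
) -> CVResult:
    """Repeated nested cross-validated ridge regression.

    Per outer fold, the inner CV selects alpha by mean inner-test Pearson r
    (ties broken toward the smaller alpha), the model is refit on the full
    outer-training fold with training-fold standardization only, and scored
    on the untouched outer-test fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= k_outer:
        raise ValueError("need n > k_outer")
    if continuous is None:
        continuous = np.array([np.unique(X[:, j]).size > 2 for j in range(p)])
    alphas = list(alphas)
    ss = np.random.SeedSequence(seed)
    repeat_seeds = ss.generate_state(2 * repeats + 1)[1:]
    records = []
    for rep in range(repeats):
        outer_seed = int(repeat_seeds[2 * rep]) % (2**31)
        inner_base = int(repeat_seeds[2 * rep + 1]) % (2**31)
        folds = continuous_stratified_folds(y, k_outer, n_bins, seed=outer_seed)
        for fold, (tr, te) in enumerate(folds):
            X_tr, X_te, y_tr, y_te = X[tr], X[te], y[tr], y[te]
            if np.std(y_tr) == 0:
                records.append(
                    dict(repeat=rep, fold=fold, pearson_r=np.nan, r2_ss=np.nan,
                         neg_mse=np.nan, alpha=np.nan, n_train=len(tr), n_test=len(te))
                )
                continue
            # inner alpha selection
            inner = continuous_stratified_folds(
                y_tr, min(k_inner, len(tr) - 1), n_bins, seed=(inner_base + fold) % (2**31)
            )
            inner_scores = np.zeros((len(alphas), len(inner)))
            for i, (itr, ite) in enumerate(inner):
                Xi_tr, Xi_te = _standardize_train_test(X_tr[itr], X_tr[ite], continuous)
                preds = _ridge_path(Xi_tr, y_tr[itr], Xi_te, alphas)
                for ai, pred in enumerate(preds):
                    if np.std(y_tr[ite]) == 0 or np.std(pred) == 0:
                        inner_scores[ai, i] = np.nan
                    else:
                        inner_scores[ai, i] = np.corrcoef(y_tr[ite], pred)[0, 1]
            mean_inner = np.nanmean(inner_scores, axis=1)
            best = 0
            for ai in range(1, len(alphas)):
                if mean_inner[ai] > mean_inner[best] + 0.0:
                    best = ai
            alpha = alphas[best]
            Xs_tr, Xs_te = _standardize_train_test(X_tr, X_te, continuous)
            pred = _ridge_path(Xs_tr, y_tr, Xs_te, [alpha])[0]
            sc = score_predictions(y_te, pred)
            records.append(
                dict(repeat=rep, fold=fold, alpha=alpha, n_train=len(tr),
                     n_test=len(te), **sc)
            )
    return CVResult(pd.DataFrame(records), feature_set=feature_set, domain=domain)


# ---------------------------------------------------------------------------
# model comparison


def corrected_ttest(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    n_train: float,
    n_test: float,
    set_a: str = "a",
    set_b: str = "b",
) -> ModelComparison:
    """Corrected resampled paired t-test over K CV scores.

    t = mean(d) / sqrt((1/K + n_test/n_train) * var(d)); two-sided p from a
    t distribution with K - 1 df. The n_test/n_train inflation accounts for
    the dependence induced by overlapping training sets.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.shape != b.shape:
        raise ValueError("score vectors must be paired and equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    d = a[ok] - b[ok]
    K = d.size
    if K < 2:
        raise ValueError("need at least 2 paired scores")
    dbar = float(d.mean())
    s2 = float(d.var(ddof=1))
    scale = float(np.abs(d).max())
    if scale == 0:
        return ModelComparison(set_a, set_b, 0.0, 1.0, 0.0)
    if math.sqrt(s2) < 1e-9 * scale:  # constant nonzero difference
        return ModelComparison(set_a, set_b, math.inf * np.sign(dbar), 1.0 / K, dbar, degenerate=True)
    t = dbar / math.sqrt((1.0 / K + n_test / n_train) * s2)
    p = 2.0 * float(stats.t.sf(abs(t), K - 1))
    return ModelComparison(set_a, set_b, float(t), p, dbar)


def naive_paired_ttest(scores_a, scores_b) -> tuple[float, float]:
    """Uncorrected paired t-test (for calibration contrasts)."""
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    d = a - b
    K = d.size
    s2 = d.var(ddof=1)
    if s2 == 0:
        return (0.0, 1.0) if d.mean() == 0 else (math.inf, 0.0)
    t = d.mean() / math.sqrt(s2 / K)
    return float(t), 2.0 * float(stats.t.sf(abs(t), K - 1))


def pairwise_comparisons(results: Mapping[str, CVResult]) -> pd.DataFrame:
    """Corrected t-tests for every ordered pair of feature sets."""
    rows = []
    names = list(results)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ra, rb = results[a], results[b]
            n_train = float(ra.records["n_train"].mean())
            n_test = float(ra.records["n_test"].mean())
            cmp = corrected_ttest(ra.scores, rb.scores, n_train, n_test, a, b)
            rows.append(
                dict(set_a=a, set_b=b, t=cmp.t, p=cmp.p, mean_diff=cmp.mean_diff,
                     degenerate=cmp.degenerate)
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# learning curve & headline ratio


def learning_curve(
    X,
    y,
    fractions: Sequence[float] | None = None,
    seed: int = 0,
    **cv_kwargs,
) -> pd.DataFrame:
    """Mean test Pearson r at random subsample fractions of the cohort.

    The desk-scale default spans 20%..100% in 10% steps (finer steps by
    config). At fraction 1.0 the full-sample CV is reproduced exactly under
    the same seed.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    if fractions is None:
        fractions = np.round(np.arange(0.2, 1.0001, 0.1), 2)
    k_outer = cv_kwargs.get("k_outer", 10)
    rows = []
    for frac in fractions:
        m = int(round(frac * n))
        if m <= k_outer:
            raise ValueError(f"fraction {frac} leaves too few samples")
        if m >= n:
            idx = np.arange(n)
        else:
            rng = np.random.default_rng(np.random.SeedSequence([seed, int(round(frac * 1000))]))
            idx = np.sort(rng.choice(n, size=m, replace=False))
        res = nested_ridge_cv(X[idx], y[idx], seed=seed, **cv_kwargs)
        rows.append(dict(fraction=float(frac), mean_pearson_r=res.mean_pearson_r, n=m))
    return pd.DataFrame(rows)


def added_performance_ratio(r_demo: float, r_imaging: float, r_lnm: float) -> float:
    """Fold-increase in added predictive performance of LNM features over a
    volumetric imaging baseline: (r_lnm - r_demo) / (r_imaging - r_demo)."""
    denom = r_imaging - r_demo
    if denom == 0:
        raise ZeroDivisionError("imaging baseline equals the demographics baseline")
    return (r_lnm - r_demo) / denom
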