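"""Linear models correlating predicted features with the recurrence score.

RS is regressed on the five Magee equation-2 variables, the three
slide-level image features, or both. OLS is the primary fit; LASSO is
used to compare which coefficients survive L1 shrinkage. Goodness of fit
is reported as R^2, adjusted R^2 and the Pearson correlation between
observed and predicted RS with its t-distribution p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

from .features import IMAGE_FEATURES, MAGEE2_FEATURES


@dataclass
class LinearModel:
    """A fitted linear RS model.

    Coefficients are always reported on the original feature scale; for
    LASSO the standardization constants used during fitting are kept so
    the fit is reproducible.
    """

    feature_names: list[str]
    intercept: float
    coefficients: pd.Series
    method: str  # "ols" | "lasso"
    lam: float | None = None
    standardization: dict | None = None
    stderr: pd.Series | None = None  # incl. "intercept" (OLS only)

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "intercept": float(self.intercept),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "method": self.method,
            "lambda": self.lam,
            "standardization": None if self.standardization is None else {
                k: {n: float(x) for n, x in v.items()}
                for k, v in self.standardization.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        std = d.get("standardization")
        return cls(
            feature_names=list(d["feature_names"]),
            intercept=float(d["intercept"]),
            coefficients=pd.Series(d["coefficients"]),
            method=d["method"],
            lam=d.get("lambda"),
            standardization=None if std is None else {
                k: pd.Series(v) for k, v in std.items()},
        )


@dataclass(frozen=True)
class FitMetrics:
    """Fit quality: R^2, adjusted R^2, Pearson r and its p-value."""

    r2: float
    adj_r2: float
    pearson_r: float
    p_value: float
    n: int
    p: int


def _as_frame(X, feature_names: Sequence[str] | None = None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X.astype(float)
    X = np.asarray(X, dtype=float)
    names = feature_names or [f"x{j}" for j in range(X.shape[1])]
    return pd.DataFrame(X, columns=list(names))


def _check_rank(X: pd.DataFrame) -> None:
    design = np.column_stack([np.ones(len(X)), X.to_numpy()])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        constant = [c for c in X.columns if X[c].nunique() <= 1]
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        collinear = [c for c in X.columns
                     if c not in constant and corr[c].max() > 1 - 1e-10]
        raise ValueError(
            f"rank-deficient design; suspect columns: {constant + collinear}"
        )


def fit_ols(X, y, feature_names: Sequence[str] | None = None) -> LinearModel:
    """Ordinary least squares with intercept.

    Raises on rank-deficient designs, naming constant/collinear columns.
    """
    Xf = _as_frame(X, feature_names)
    y = np.asarray(y, dtype=float)
    if len(Xf) <= Xf.shape[1] + 1:
        raise ValueError("need n > p + 1 observations")
    _check_rank(Xf)
    res = sm.OLS(y, sm.add_constant(Xf, prepend=True)).fit()
    params = res.params
    stderr = res.bse.rename(index={"const": "intercept"})
    return LinearModel(
        feature_names=list(Xf.columns),
        intercept=float(params["const"]),
        coefficients=params.drop("const"),
        method="ols",
        stderr=stderr,
    )


def _lasso_standardized(Xs: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Slopes and intercept of the L1 fit on an already-standardized design."""
    if lam == 0.0:
        # unpenalized limit: plain least squares on the standardized design
        design = np.column_stack([np.ones(len(Xs)), Xs])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        return beta[1:], float(beta[0])
    est = Lasso(alpha=lam, fit_intercept=True, max_iter=100_000, tol=1e-10)
    est.fit(Xs, y)
    return est.coef_, float(est.intercept_)


def fit_lasso(X, y, lam: float | str = "cv",
              feature_names: Sequence[str] | None = None,
              seed: int = 0, n_folds: int = 5) -> LinearModel:
    """L1-penalized fit on z-scored features, intercept unpenalized.

    ``lam`` is the scikit-learn penalty scale (objective
    (1/2n)*RSS + lam*||beta||_1) or ``"cv"``: seeded ``n_folds``-fold
    cross-validation minimizing MSE with the one-standard-error rule
    (largest penalty within one SE of the minimum mean MSE).
    Coefficients are reported back on the original feature scale.
    """
    Xf = _as_frame(X, feature_names)
    y = np.asarray(y, dtype=float)
    mu = Xf.mean()
    sd = Xf.std(ddof=0)
    if (sd == 0).any():
        raise ValueError(f"constant features cannot be standardized: "
                         f"{list(sd.index[sd == 0])}")
    Xs = ((Xf - mu) / sd).to_numpy()

    if isinstance(lam, str):
        if lam != "cv":
            raise ValueError("lam must be a non-negative number or 'cv'")
        lam = _lasso_cv_lambda(Xs, y, seed=seed, n_folds=n_folds)
    elif lam < 0:
        raise ValueError("lambda must be non-negative")

    slopes_std, icpt_std = _lasso_standardized(Xs, y, float(lam))
    slopes = slopes_std / sd.to_numpy()
    intercept = icpt_std - float(np.sum(slopes * mu.to_numpy()))
    return LinearModel(
        feature_names=list(Xf.columns),
        intercept=intercept,
        coefficients=pd.Series(slopes, index=Xf.columns),
        method="lasso",
        lam=float(lam),
        standardization={"mean": mu, "sd": sd},
    )


def _lasso_cv_lambda(Xs: np.ndarray, y: np.ndarray, seed: int,
                     n_folds: int) -> float:
    """Pick the penalty by K-fold CV with the 1-SE rule."""
    lam_max = np.max(np.abs(Xs.T @ (y - y.mean()))) / len(y)
    grid = lam_max * np.logspace(0, -3, 60)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    mse = np.empty((len(grid), n_folds))
    for j, (tr, te) in enumerate(kf.split(Xs)):
        for i, lam in enumerate(grid):
            slopes, icpt = _lasso_standardized(Xs[tr], y[tr], float(lam))
            pred = Xs[te] @ slopes + icpt
            mse[i, j] = np.mean((y[te] - pred) ** 2)
    mean = mse.mean(axis=1)
    se = mse.std(axis=1, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(mean))
    admissible = np.flatnonzero(mean <= mean[i_min] + se[i_min])
    return float(grid[admissible.min()])  # grid is decreasing: min index = largest lam


def predict_rs(model: LinearModel, X) -> np.ndarray:
    """Raw (unclamped) linear predictions; feature names must match."""
    Xf = _as_frame(X, model.feature_names if not isinstance(X, pd.DataFrame) else None)
    missing = [f for f in model.feature_names if f not in Xf.columns]
    if missing:
        raise ValueError(f"features missing from input: {missing}")
    Xf = Xf[model.feature_names]
    return model.intercept + Xf.to_numpy() @ model.coefficients.to_numpy()


def fit_metrics(y_true, y_pred, p: int) -> FitMetrics:
    """R^2, adjusted R^2 and Pearson correlation with p-value.

    R^2 = 1 - SS_res/SS_tot; adjusted R^2 = 1 - (1-R^2)(n-1)/(n-p-1);
    the Pearson p-value is two-sided from t = r*sqrt((n-2)/(1-r^2)) on
    n-2 degrees of freedom.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    n = len(y_true)
    if n <= p + 1:
        raise ValueError("need n > p + 1 observations")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("y_true has zero variance")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    if np.ptp(y_pred) == 0:
        r, pval = 0.0, 1.0
    else:
        r, pval = stats.pearsonr(y_true, y_pred)
    return FitMetrics(r2=r2, adj_r2=adj_r2, pearson_r=float(r),
                      p_value=float(pval), n=n, p=p)


FEATURE_SETS = {
    "magee2": list(MAGEE2_FEATURES),
    "image": list(IMAGE_FEATURES),
    "combined": list(MAGEE2_FEATURES) + list(IMAGE_FEATURES),
}


def tile_feature_names(depth: int) -> list[str]:
    """Column names of the tile-wise triplets for tiles 1..depth."""
    names = []
    for i in range(1, depth + 1):
        names += [f"t{i:02d}_tumor", f"t{i:02d}_til", f"t{i:02d}_pct"]
    return names


@dataclass(frozen=True)
class CombinationResult:
    features: list[str]
    adj_r2: float
    depth: int
    use_variance: bool
    use_grade: bool


def search_feature_combinations(
    table: pd.DataFrame,
    y,
    base_features: Sequence[str] = MAGEE2_FEATURES,
    max_depth: int = 10,
    variance_col: str = "til_var",
    grade_col: str = "nuc_grade",
) -> tuple[CombinationResult, pd.DataFrame]:
    """Exhaustive search over tile depth x V/G inclusion by adjusted R^2.

    Candidate models use the base (Magee) variables, the tile-wise
    triplets of the first x tiles (x = 1..max_depth) and optionally the
    TIL number variance and/or the aggregated nuclear grade. Models are
    fit by OLS on ``table``/``y`` and scored by training adjusted R^2;
    ties break toward fewer features. Returns the winner and the full
    scored grid.
    """
    y = np.asarray(y, dtype=float)
    rows = []
    best: CombinationResult | None = None
    for depth, use_v, use_g in product(range(1, max_depth + 1), (False, True),
                                       (False, True)):
        feats = list(base_features) + tile_feature_names(depth)
        if use_v:
            feats.append(variance_col)
        if use_g:
            feats.append(grade_col)
        if len(table) <= len(feats) + 1:
            continue
        try:
            model = fit_ols(table[feats], y)
        except ValueError:
            continue
        m = fit_metrics(y, predict_rs(model, table[feats]), p=len(feats))
        res = CombinationResult(features=feats, adj_r2=m.adj_r2, depth=depth,
                                use_variance=use_v, use_grade=use_g)
        rows.append({"depth": depth, "use_variance": use_v, "use_grade": use_g,
                     "n_features": len(feats), "adj_r2": m.adj_r2})
        if (best is None or res.adj_r2 > best.adj_r2
                or (res.adj_r2 == best.adj_r2
                    and len(res.features) < len(best.features))):
            best = res
    if best is None:
        raise ValueError("no admissible feature combination (n too small)")
    return best, pd.DataFrame(rows)
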