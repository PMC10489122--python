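"""Leakage-guarded univariate feature screening with train-split z-scoring.

Inside each cross-validation fold the feature set is reduced before the
classifier sees it: every feature is regressed on the genotype group
plus the nuisance covariates age, sex and education (an ordinary linear
model; the group term's two-sided p-value is the screen statistic), and
only features with p below a threshold are kept.  Both the kept-feature
mask and the normalisation constants (per-feature mean and standard
deviation) are computed on the *training* rows only and then applied
unchanged to the held-out rows — the held-out labels and values can
never influence selection or scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

COVARIATE_COLUMNS = ("age", "sex", "education")


def _as_2d(X) -> tuple[np.ndarray, list[str] | None]:
    """Coerce to a float matrix; names are None for plain arrays."""
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    return X, None


def _covariate_array(covariates) -> np.ndarray:
    if isinstance(covariates, pd.DataFrame):
        cols = [c for c in COVARIATE_COLUMNS if c in covariates.columns]
        if len(cols) == len(COVARIATE_COLUMNS):
            return covariates[list(COVARIATE_COLUMNS)].to_numpy(dtype=float)
        return covariates.to_numpy(dtype=float)
    return np.asarray(covariates, dtype=float)


def glm_group_pvalues(
    features: np.ndarray, group: np.ndarray, covariates: np.ndarray
) -> np.ndarray:
    """Two-sided p-value of the group term, one linear model per feature.

    Fits ``feature ~ 1 + group + covariates`` by least squares for every
    column of ``features`` simultaneously and returns the p-value of the
    group coefficient's t-test.  Constant features get p = 1.
    """
    Y = np.asarray(features, dtype=float)
    if Y.ndim == 1:
        Y = Y.reshape(-1, 1)
    group = np.asarray(group, dtype=float).ravel()
    C = _covariate_array(covariates)
    if C.ndim == 1:
        C = C.reshape(-1, 1)
    n = Y.shape[0]
    X = np.column_stack([np.ones(n), group, C])
    p = X.shape[1]
    if n <= p + 1:
        raise ValueError(f"need more than {p + 1} observations, got {n}")
    if len(np.unique(group)) < 2:
        raise ValueError("group must contain both classes")

    XtX = X.T @ X
    XtX_inv = np.linalg.pinv(XtX)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    dof = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / se, 0.0)
    return 2.0 * stats.t.sf(np.abs(t), dof)


def glm_group_pvalue(feature, group, covariates) -> float:
    """Group-term p-value for a single feature (see :func:`glm_group_pvalues`)."""
    return float(glm_group_pvalues(np.asarray(feature, dtype=float), group, covariates)[0])


@dataclass
class SelectionResult:
    """Per-feature screening outcome for one training split."""

    feature_names: list[str]
    pvalues: np.ndarray
    keep: np.ndarray  # boolean mask over feature_names
    train_mean: np.ndarray  # over kept features
    train_sd: np.ndarray  # over kept features

    @property
    def kept_names(self) -> list[str]:
        return [n for n, k in zip(self.feature_names, self.keep) if k]

    def to_frame(self) -> pd.DataFrame:
        """Tab-separable per-fold report: feature, p, kept, train stats."""
        mean = np.full(len(self.feature_names), np.nan)
        sd = np.full(len(self.feature_names), np.nan)
        mean[self.keep] = self.train_mean
        sd[self.keep] = self.train_sd
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "p_value": self.pvalues,
                "kept": self.keep,
                "train_mean": mean,
                "train_sd": sd,
            }
        )


class FeatureScreener(BaseEstimator, TransformerMixin):
    """Covariate-adjusted univariate screen + z-scoring, fit on training rows.

    Parameters
    ----------
    alpha : float
        Keep features whose group-term p-value is strictly below this.

    Attributes (after ``fit``)
    --------------------------
    pvalues_ : per-feature screen p-values
    keep_mask_ : boolean mask of kept features
    means_, sds_ : normalisation constants of kept features
    n_kept_ : number of surviving features
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y, covariates=None):
        if covariates is None:
            raise ValueError("covariates (age, sex, education) are required")
        Xa, names = _as_2d(X)
        y = np.asarray(y).ravel()
        if Xa.shape[0] != y.shape[0]:
            raise ValueError("X and y have different numbers of rows")
        if names is None:
            names = [f"f{j}" for j in range(Xa.shape[1])]
        self.feature_names_in_ = names
        self.pvalues_ = glm_group_pvalues(Xa, y, covariates)
        keep = self.pvalues_ < self.alpha

        sds = Xa.std(axis=0, ddof=1)
        degenerate = keep & (sds == 0)
        if degenerate.any():
            bad = [names[j] for j in np.flatnonzero(degenerate)]
            warnings.warn(f"dropping zero-variance feature(s): {bad}", stacklevel=2)
            keep = keep & (sds > 0)

        self.keep_mask_ = keep
        self.means_ = Xa[:, keep].mean(axis=0)
        self.sds_ = sds[keep]
        self.n_kept_ = int(keep.sum())
        return self

    def transform(self, X):
        Xa, names = _as_2d(X)
        if Xa.shape[1] != len(self.feature_names_in_) or (
            names is not None and names != self.feature_names_in_
        ):
            raise ValueError("feature columns do not match the fitted screen")
        Z = (Xa[:, self.keep_mask_] - self.means_) / self.sds_
        return Z

    def selection_result_(self) -> SelectionResult:
        return SelectionResult(
            feature_names=list(self.feature_names_in_),
            pvalues=self.pvalues_.copy(),
            keep=self.keep_mask_.copy(),
            train_mean=self.means_.copy(),
            train_sd=self.sds_.copy(),
        )


def select_and_normalize(
    train_X,
    train_y,
    train_covariates,
    apply_X,
    alpha: float = 0.05,
) -> tuple[SelectionResult, np.ndarray, np.ndarray]:
    """Screen on the training split and z-score both splits with its statistics.

    Returns ``(selection, normalized_train, normalized_apply)``; the
    kept-feature set is identical for both splits by construction.
    """
    screener = FeatureScreener(alpha=alpha).fit(train_X, train_y, covariates=train_covariates)
    return screener.selection_result_(), screener.transform(train_X), screener.transform(apply_X)
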