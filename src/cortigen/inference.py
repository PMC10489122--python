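"""Group-difference and gene-gene interaction statistics.

Three layers of inference sit on top of the feature tables and the
cluster distances:

* a mass-univariate scan — each of the 286 features regressed on one
  genotype flag with age/sex/education as covariates (plus total
  intracranial volume for volumetric features), Benjamini-Hochberg FDR
  across all tested features;
* interaction models — per cluster, ``distance ~ apoe + mapt +
  apoe:mapt + age + sex + education`` by ordinary least squares, the
  interaction term Bonferroni-corrected over the number of clusters;
* follow-up models — the same interaction design on the per-participant
  mean of a single metric over one cluster's regions.

Genotype flags are coded 0/1 with a product interaction; tests are
two-sided at the 0.05 level throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .atlas import parse_feature_name
from .ghsom import ClusterAssignment
from .screening import glm_group_pvalues

INTERACTION_TERM = "apoe:mapt"
_COVARS = ("age", "sex", "education")


@dataclass
class GLMResult:
    """Ordinary-least-squares fit of one interaction model."""

    outcome: str
    terms: list[str]
    estimates: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    n: int
    degenerate: bool = False

    def term(self, name: str) -> dict[str, float]:
        i = self.terms.index(name)
        return {
            "estimate": float(self.estimates[i]),
            "t": float(self.tvalues[i]),
            "p": float(self.pvalues[i]),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.terms, "estimate": self.estimates,
             "t": self.tvalues, "p": self.pvalues}
        )


@dataclass
class CorrectionReport:
    """Raw and multiplicity-adjusted p-values with 0.05 rejection flags."""

    names: list[str]
    raw_pvalues: np.ndarray
    adjusted_pvalues: np.ndarray
    method: str  # "fdr_bh" or "bonferroni"
    reject: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.reject is None:
            self.reject = self.adjusted_pvalues < 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"name": self.names, "p_raw": self.raw_pvalues,
             "p_adjusted": self.adjusted_pvalues, "reject": self.reject}
        )


def adjust_pvalues(pvalues, method: str = "fdr_bh", names=None) -> CorrectionReport:
    """Benjamini-Hochberg or Bonferroni adjustment at the 0.05 level."""
    pvalues = np.asarray(pvalues, dtype=float)
    if method not in ("fdr_bh", "bonferroni"):
        raise ValueError("method must be 'fdr_bh' or 'bonferroni'")
    if pvalues.size == 0:
        return CorrectionReport([], pvalues, pvalues.copy(), method)
    reject, adjusted, _, _ = multipletests(pvalues, alpha=0.05, method=method)
    if names is None:
        names = [f"p{i}" for i in range(pvalues.size)]
    return CorrectionReport(list(names), pvalues, adjusted, method, reject)


def univariate_scan(
    features: pd.DataFrame,
    genotype,
    covariates: pd.DataFrame,
    tiv=None,
) -> CorrectionReport:
    """Covariate-adjusted group comparison of every feature, FDR-corrected.

    Volume-type features (subcortical volumes) are additionally adjusted
    for total intracranial volume, taken from ``tiv`` or from a ``tiv``
    column of ``covariates``.  Constant features are skipped with a
    warning and excluded from the correction.
    """
    genotype = np.asarray(genotype).astype(int).ravel()
    base_cov = covariates[list(_COVARS)].to_numpy(dtype=float)
    if tiv is None and "tiv" in covariates.columns:
        tiv = covariates["tiv"]
    names = list(features.columns)
    is_volume = np.array([parse_feature_name(n)[2] == "volume" for n in names])

    values = features.to_numpy(dtype=float)
    sds = values.std(axis=0)
    constant = sds == 0
    if constant.any():
        warnings.warn(
            f"skipping constant feature(s): {[names[j] for j in np.flatnonzero(constant)][:5]}",
            stacklevel=2,
        )

    pvals = np.full(len(names), np.nan)
    plain = ~is_volume & ~constant
    if plain.any():
        pvals[plain] = glm_group_pvalues(values[:, plain], genotype, base_cov)
    vol = is_volume & ~constant
    if vol.any():
        if tiv is None:
            raise ValueError("total intracranial volume required to test volume features")
        cov_tiv = np.column_stack([base_cov, np.asarray(tiv, dtype=float)])
        pvals[vol] = glm_group_pvalues(values[:, vol], genotype, cov_tiv)

    tested = ~constant
    return adjust_pvalues(
        pvals[tested], method="fdr_bh", names=[n for n, t in zip(names, tested) if t]
    )


def _interaction_design(apoe, mapt, covariates: pd.DataFrame) -> pd.DataFrame:
    apoe = np.asarray(apoe).astype(int).ravel()
    mapt = np.asarray(mapt).astype(int).ravel()
    cells = {(a, m): int(((apoe == a) & (mapt == m)).sum()) for a in (0, 1) for m in (0, 1)}
    empty = [cell for cell, n in cells.items() if n == 0]
    if empty:
        raise ValueError(f"empty genotype cell(s) (apoe, mapt): {empty}")
    X = pd.DataFrame(
        {
            "apoe": apoe,
            "mapt": mapt,
            INTERACTION_TERM: apoe * mapt,
            "age": covariates["age"].to_numpy(dtype=float),
            "sex": covariates["sex"].to_numpy(dtype=float),
            "education": covariates["education"].to_numpy(dtype=float),
        }
    )
    return sm.add_constant(X)


def _fit_glm(outcome_name: str, y: np.ndarray, design: pd.DataFrame) -> GLMResult:
    y = np.asarray(y, dtype=float).ravel()
    degenerate = bool(np.std(y) == 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.OLS(y, design).fit()
    tvals = np.nan_to_num(fit.tvalues.to_numpy(), nan=0.0)
    pvals = np.nan_to_num(fit.pvalues.to_numpy(), nan=1.0)
    if degenerate:
        # a constant outcome carries no evidence; numerical round-off in
        # the zero-residual fit would otherwise produce arbitrary t values
        tvals = np.zeros_like(tvals)
        pvals = np.ones_like(pvals)
    return GLMResult(
        outcome=outcome_name,
        terms=list(design.columns),
        estimates=fit.params.to_numpy(),
        tvalues=tvals,
        pvalues=pvals,
        n=len(y),
        degenerate=degenerate,
    )


def interaction_glm(
    distances: pd.DataFrame,
    apoe,
    mapt,
    covariates: pd.DataFrame,
) -> tuple[list[GLMResult], CorrectionReport]:
    """Gene-gene interaction on each cluster's intra-cluster distance.

    Fits ``distance ~ apoe + mapt + apoe:mapt + age + sex + education``
    per cluster and Bonferroni-corrects the interaction-term p-values
    over the number of clusters.  Constant distance columns are fitted
    but flagged degenerate (t forced to 0, p to 1).
    """
    design = _interaction_design(apoe, mapt, covariates)
    results = [
        _fit_glm(col, distances[col].to_numpy(dtype=float), design) for col in distances.columns
    ]
    raw = np.array([r.term(INTERACTION_TERM)["p"] for r in results])
    report = adjust_pvalues(raw, method="bonferroni", names=list(distances.columns))
    return results, report


def cluster_metric_glm(
    features: pd.DataFrame,
    assignment: ClusterAssignment,
    cluster: int,
    metric: str,
    apoe,
    mapt,
    covariates: pd.DataFrame,
) -> GLMResult:
    """Interaction model on the mean of one metric over one cluster's regions."""
    members = assignment.members(cluster)
    if not members:
        raise ValueError(f"cluster {cluster} has no member regions")
    cols = [f"{r}_{metric}" for r in members]
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValueError(f"feature matrix lacks column(s) {missing[:3]}")
    y = features[cols].to_numpy(dtype=float).mean(axis=1)
    design = _interaction_design(apoe, mapt, covariates)
    return _fit_glm(f"cluster{cluster}_mean_{metric}", y, design)
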