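"""Genotype classification: stratified 5-fold linear SVM with permutation tests.

The discriminative pipeline asks whether regional morphometry carries
information about carrier status.  Within each of k stratified folds the
training split is screened (covariate-adjusted univariate filter) and
z-scored with training statistics, a linear soft-margin SVM (C = 1) is
fitted, and the held-out rows are predicted.  Held-out predictions are
pooled over folds into a single confusion matrix before any metric is
computed, so every participant contributes exactly one prediction.

Because carrier classes are unbalanced, the report includes positive and
negative predictive value and the F-score alongside accuracy,
sensitivity, specificity and AUC.  Significance of each metric is
assessed by re-running the entire pipeline (screening included) under
label permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import rankdata
from sklearn import config_context
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .screening import FeatureScreener, SelectionResult, _as_2d, _covariate_array

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "auc", "ppv", "npv", "f_score")


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero, as results tables are printed."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """Pooled binary confusion counts (hit / miss / correct rejection / false alarm)."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int).ravel()
        y_pred = np.asarray(y_pred).astype(int).ravel()
        if y_true.shape != y_pred.shape:
            raise ValueError("label vectors differ in length")
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        )


def _safe_ratio(num: float, den: float, undefined: set[str], name: str) -> float:
    if den == 0:
        undefined.add(name)
        return 0.0
    return num / den


def compute_metrics(
    counts: ConfusionCounts,
    decision_values=None,
    labels=None,
) -> tuple[dict[str, float], set[str]]:
    """The seven performance metrics from pooled counts and decision values.

    accuracy = (TP+TN)/(TP+FN+TN+FP); sensitivity = TP/(TP+FN);
    specificity = TN/(TN+FP); PPV = TP/(TP+FP); NPV = TN/(TN+FN);
    F = 2*PPV*sensitivity/(PPV+sensitivity); AUC from the pooled
    decision values (omitted if none are given).  Ratios with a zero
    denominator are reported as 0 and flagged in the returned set.
    """
    undefined: set[str] = set()
    c = counts
    metrics = {
        "accuracy": _safe_ratio(c.tp + c.tn, c.n, undefined, "accuracy"),
        "sensitivity": _safe_ratio(c.tp, c.tp + c.fn, undefined, "sensitivity"),
        "specificity": _safe_ratio(c.tn, c.tn + c.fp, undefined, "specificity"),
        "ppv": _safe_ratio(c.tp, c.tp + c.fp, undefined, "ppv"),
        "npv": _safe_ratio(c.tn, c.tn + c.fn, undefined, "npv"),
    }
    denom = metrics["ppv"] + metrics["sensitivity"]
    metrics["f_score"] = _safe_ratio(2 * metrics["ppv"] * metrics["sensitivity"], denom, undefined, "f_score")
    if decision_values is not None and labels is not None:
        labels = np.asarray(labels).astype(int).ravel()
        n_pos = int((labels == 1).sum())
        n_neg = labels.size - n_pos
        if n_pos == 0 or n_neg == 0:
            undefined.add("auc")
            metrics["auc"] = 0.0
        else:
            # Mann-Whitney form of the ROC area, with midranks for ties
            ranks = rankdata(np.asarray(decision_values, dtype=float))
            metrics["auc"] = float(
                (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
            )
    return metrics, undefined


def confusion_from_rates(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int, decimals: int = 2
) -> ConfusionCounts:
    """Reconstruct integer confusion counts from printed sensitivity/specificity.

    Finds the integer TP (resp. TN) whose ratio to the class size rounds
    (half-up) to the printed value at the given precision; raises if no
    candidate or more than one exists, since the reconstruction is only
    meaningful when it is unique.
    """
    tp_candidates = [
        t for t in range(n_pos + 1) if round_half_up(t / n_pos, decimals) == round_half_up(sensitivity, decimals)
    ]
    tn_candidates = [
        t for t in range(n_neg + 1) if round_half_up(t / n_neg, decimals) == round_half_up(specificity, decimals)
    ]
    if len(tp_candidates) != 1 or len(tn_candidates) != 1:
        raise ValueError(
            f"printed rates do not determine a unique confusion matrix "
            f"(TP candidates {tp_candidates}, TN candidates {tn_candidates})"
        )
    tp, tn = tp_candidates[0], tn_candidates[0]
    return ConfusionCounts(tp=tp, fn=n_pos - tp, tn=tn, fp=n_neg - tn)


def stratified_folds(labels, k: int = 5, seed: int | None = None) -> np.ndarray:
    """Stratified random fold assignment (0..k-1) with balanced class proportions.

    Fold sizes differ by at most one, as do per-fold positive counts.
    ``k = 1`` degenerates to a single fold covering the whole sample.
    """
    labels = np.asarray(labels).astype(int).ravel()
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.zeros(labels.shape[0], dtype=int)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} members, fewer than k={k} folds")
    assignment = np.empty(labels.shape[0], dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=None if seed is None else int(seed) % (2**32))
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(labels.shape[0]), labels)):
        assignment[test_idx] = fold
    return assignment


@dataclass
class ClassificationReport:
    """Pooled cross-validated performance of the screened linear SVM."""

    counts: ConfusionCounts
    metrics: dict[str, float]
    undefined: set[str]
    fold_assignment: np.ndarray
    y_pred: np.ndarray
    decision_values: np.ndarray
    permutation_pvalues: dict[str, float] | None = None
    n_permutations: int | None = None

    def rounded(self, decimals: int = 2) -> dict[str, float]:
        """Metrics rounded half-up, as presented in results tables."""
        return {k: round_half_up(v, decimals) for k, v in self.metrics.items()}

    def to_json_dict(self) -> dict:
        out = {
            "counts": {"tp": self.counts.tp, "fn": self.counts.fn, "tn": self.counts.tn, "fp": self.counts.fp},
            "metrics": {k: float(v) for k, v in self.metrics.items()},
            "undefined": sorted(self.undefined),
        }
        if self.permutation_pvalues is not None:
            out["permutation_pvalues"] = {k: float(v) for k, v in self.permutation_pvalues.items()}
            out["n_permutations"] = self.n_permutations
        return out


class ScreenedLinearSVM:
    """Screen -> z-score -> linear SVM, fit on one training split.

    A minimal estimator: ``fit(X, y, covariates=...)`` screens features
    with the covariate-adjusted filter, normalises with training
    statistics and fits ``SVC(kernel='linear', C=C)``.  If the screen
    keeps no features the model falls back to predicting the training
    majority class with zero decision values.
    """

    def __init__(self, C: float = 1.0, alpha: float = 0.05):
        self.C = C
        self.alpha = alpha

    def get_params(self, deep: bool = True) -> dict:
        return {"C": self.C, "alpha": self.alpha}

    def set_params(self, **params) -> "ScreenedLinearSVM":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y, covariates=None):
        y = np.asarray(y).astype(int).ravel()
        self.screener_ = FeatureScreener(alpha=self.alpha).fit(X, y, covariates=covariates)
        self.n_features_in_ = len(self.screener_.feature_names_in_)
        if self.screener_.n_kept_ == 0:
            self.svc_ = None
            self.majority_ = int(np.bincount(y, minlength=2).argmax())
            self.coef_full_ = np.zeros(self.n_features_in_)
            return self
        Z = self.screener_.transform(X)
        self.svc_ = SVC(kernel="linear", C=self.C)
        with config_context(assume_finite=True):
            self.svc_.fit(Z, y)
        # hyperplane cached so prediction avoids the estimator round-trip;
        # SVC orders classes_ ascending, so decision > 0 means class 1
        self._w = self.svc_.coef_.ravel()
        self._b = float(self.svc_.intercept_[0])
        coef = np.zeros(self.n_features_in_)
        coef[self.screener_.keep_mask_] = self._w
        self.coef_full_ = coef
        return self

    def predict(self, X) -> np.ndarray:
        if self.svc_ is None:
            return np.full(_as_2d(X)[0].shape[0], self.majority_, dtype=int)
        return (self.decision_function(X) > 0).astype(int)

    def decision_function(self, X) -> np.ndarray:
        if self.svc_ is None:
            return np.zeros(_as_2d(X)[0].shape[0])
        return self.screener_.transform(X) @ self._w + self._b


def cv_classify(
    features,
    labels,
    covariates,
    k: int = 5,
    C: float = 1.0,
    alpha: float = 0.05,
    seed: int | None = None,
    fold_assignment: np.ndarray | None = None,
    collect_selections: bool = False,
) -> tuple[ClassificationReport, list[np.ndarray], list[SelectionResult]]:
    """Stratified k-fold screened-SVM classification with pooled evaluation.

    Returns the pooled :class:`ClassificationReport`, the per-fold
    hyperplane weights re-expanded to full feature space (zeros for
    unselected features), and — if requested — the per-fold screening
    reports.  Screening and normalisation are fitted inside each fold on
    its training rows only.
    """
    X, _ = _as_2d(features)
    y = np.asarray(labels).astype(int).ravel()
    Cov = _covariate_array(covariates)
    if fold_assignment is None:
        fold_assignment = stratified_folds(y, k=k, seed=seed)
    else:
        fold_assignment = np.asarray(fold_assignment, dtype=int)
    n = y.shape[0]
    y_pred = np.empty(n, dtype=int)
    decision = np.empty(n, dtype=float)
    fold_weights: list[np.ndarray] = []
    selections: list[SelectionResult] = []

    with config_context(assume_finite=True, skip_parameter_validation=True):
        for fold in np.unique(fold_assignment):
            test = fold_assignment == fold
            train = ~test if fold_assignment.max() > 0 else np.ones(n, dtype=bool)
            model = ScreenedLinearSVM(C=C, alpha=alpha)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[train], y[train], covariates=Cov[train])
            y_pred[test] = model.predict(X[test])
            decision[test] = model.decision_function(X[test])
            fold_weights.append(model.coef_full_)
            if collect_selections:
                selections.append(model.screener_.selection_result_())

    counts = ConfusionCounts.from_predictions(y, y_pred)
    metrics, undefined = compute_metrics(counts, decision, y)
    report = ClassificationReport(
        counts=counts,
        metrics=metrics,
        undefined=undefined,
        fold_assignment=fold_assignment,
        y_pred=y_pred,
        decision_values=decision,
    )
    return report, fold_weights, selections


def permutation_test(
    features,
    labels,
    covariates,
    n_perm: int = 1000,
    k: int = 5,
    C: float = 1.0,
    alpha: float = 0.05,
    seed: int | None = None,
    tie_rule: str = "strict",
) -> ClassificationReport:
    """Permutation significance of every pooled metric.

    The full pipeline — fold splitting, within-fold screening,
    normalisation, SVM — is re-run on each of ``n_perm`` label
    permutations.  With the literal ``strict`` rule the p-value of a
    metric is the proportion of permutations whose null metric exceeds
    the observed one (which can be exactly 0); ``plus_one`` applies the
    standard (r+1)/(n_perm+1) correction that guarantees p > 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tie_rule not in ("strict", "plus_one"):
        raise ValueError("tie_rule must be 'strict' or 'plus_one'")
    rng = np.random.default_rng(seed)
    fold_seed = int(rng.integers(2**31))
    report, _, _ = cv_classify(features, labels, covariates, k=k, C=C, alpha=alpha, seed=fold_seed)
    y = np.asarray(labels).astype(int).ravel()

    exceed = {m: 0 for m in report.metrics}
    exceed_eq = {m: 0 for m in report.metrics}
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        perm_report, _, _ = cv_classify(
            features, y_perm, covariates, k=k, C=C, alpha=alpha, seed=int(rng.integers(2**31))
        )
        for m, v in perm_report.metrics.items():
            if v > report.metrics[m]:
                exceed[m] += 1
            if v >= report.metrics[m]:
                exceed_eq[m] += 1

    if tie_rule == "strict":
        pvals = {m: exceed[m] / n_perm for m in exceed}
    else:
        pvals = {m: (exceed_eq[m] + 1) / (n_perm + 1) for m in exceed_eq}
    report.permutation_pvalues = pvals
    report.n_permutations = n_perm
    return report
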