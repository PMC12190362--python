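"""Failure self-reporting, the failureAlert forest, and evaluation statistics.

The vessel-feature method can detect its own failures (no matches, or
too few MSAC inliers to estimate a homography).  The affine backend
cannot, so a 500-tree random forest is fit on the affine covariates
(similarity, NMI, overlap percentage, translations, rotation, skew)
with registration success as the outcome; *failureAlert* is 1 minus the
fraction of trees voting success.  The *overlapdiff* statistic — the
absolute difference between the two methods' overlap percentages for
the same eye — cross-checks the methods against each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score

from .errors import InputError, UndefinedValueError

ALL_COVARIATES = ("similarity", "nmi", "overlap_pct", "tx", "ty", "rotation", "skew")
#: reduced covariate set used when the caller skips variable selection
DEFAULT_SELECTED = ("similarity", "nmi", "overlap_pct", "tx", "skew")


@dataclass
class RegistrationReport:
    """Per-method outcome for one image pair."""

    method: str                         # "vessel" | "affine_nmi"
    success_flag: bool | None = None    # external (e.g. visual) label, if any
    self_reported_failure: bool = False
    failure_reason: str = ""
    n_matches: int | None = None
    n_inliers: int | None = None
    covariates: dict = field(default_factory=dict)
    overlap_pct: float | None = None
    failure_alert: float | None = None
    transform: object = None            # HomographyTransform or AffineTransform

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "self_reported_failure": self.self_reported_failure,
            "failure_reason": self.failure_reason,
            "n_matches": self.n_matches,
            "n_inliers": self.n_inliers,
            "overlap_pct": self.overlap_pct,
            "failure_alert": self.failure_alert,
            "covariates": {k: float(v) for k, v in self.covariates.items()},
        }


@dataclass
class ContingencySummary:
    """2x2 success/failure cross-table of two methods; every percentage is
    recomputed from the integer cells."""

    cells: np.ndarray  # [[a_s & b_s, a_s & b_f], [a_f & b_s, a_f & b_f]]

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if self.cells.shape != (2, 2) or (self.cells < 0).any():
            raise InputError("cells must be a 2x2 array of non-negative counts")

    @property
    def total(self) -> int:
        return int(self.cells.sum())

    @property
    def method_a_success_pct(self) -> float:
        return 100.0 * self.cells[0].sum() / self.total

    @property
    def method_b_success_pct(self) -> float:
        return 100.0 * self.cells[:, 0].sum() / self.total

    @property
    def joint_failure_pct(self) -> float:
        return 100.0 * self.cells[1, 1] / self.total

    @property
    def at_least_one_success_pct(self) -> float:
        return 100.0 * (self.total - self.cells[1, 1]) / self.total

    def as_dict(self) -> dict:
        return {
            "cells": self.cells.tolist(),
            "total": self.total,
            "method_a_success_pct": round(self.method_a_success_pct, 1),
            "method_b_success_pct": round(self.method_b_success_pct, 1),
            "joint_failure_pct": round(self.joint_failure_pct, 1),
            "at_least_one_success_pct": round(self.at_least_one_success_pct, 1),
        }


@dataclass
class FailureModel:
    forest: RandomForestClassifier
    selected_covariates: tuple[str, ...]
    n_trees: int = 500
    oob_auc: float = float("nan")


def self_report(n_matches: int, n_inliers: int, min_inliers: int = 4) -> bool:
    """True (failure) iff no matches were found or too few inliers remain
    to estimate the minimal 4-point homography."""
    if n_matches < 0 or n_inliers < 0:
        raise InputError("counts must be non-negative")
    return n_matches == 0 or n_inliers < min_inliers


def overlapdiff(report_a: RegistrationReport | float,
                report_b: RegistrationReport | float) -> float:
    """Absolute difference of the two methods' overlap, in percentage points."""
    def pct(r):
        if isinstance(r, RegistrationReport):
            if r.overlap_pct is None:
                raise UndefinedValueError(f"report ({r.method}) carries no overlap")
            v = r.overlap_pct
        else:
            v = float(r)
        return 100.0 * v if v <= 1.0 else v
    return abs(pct(report_a) - pct(report_b))


def unaware_failure_pct(n_failures: int, n_self_reported: int, n_total: int) -> float:
    """Share of all eyes on which a method failed *without* reporting it."""
    if not (0 <= n_self_reported <= n_failures <= n_total):
        raise InputError("need 0 <= self-reported <= failures <= total")
    return 100.0 * (n_failures - n_self_reported) / n_total


def train_failure_forest(covariate_table: pd.DataFrame, labels: np.ndarray,
                         n_trees: int = 500, seed: int = 0,
                         importance_fraction: float = 0.10) -> FailureModel:
    """Fit the 500-tree success/failure forest with importance-based selection.

    Covariates whose permutation importance exceeds ``importance_fraction``
    of the maximum are retained and the forest is refit on them.  Labels:
    True = success.  Deterministic under ``seed``.
    """
    labels = np.asarray(labels, bool)
    if len(covariate_table) < 50:
        raise InputError(f"need >= 50 rows, got {len(covariate_table)}")
    if labels.shape[0] != len(covariate_table):
        raise InputError("labels and covariate rows mismatch")
    if labels.all() or not labels.any():
        raise InputError("both outcome classes must be present")
    X = covariate_table[list(covariate_table.columns)].to_numpy(float)
    y = labels.astype(int)

    def fit(Xs: np.ndarray) -> RandomForestClassifier:
        rf = RandomForestClassifier(n_estimators=n_trees, oob_score=True,
                                    random_state=seed, n_jobs=1)
        rf.fit(Xs, y)
        return rf

    full = fit(X)
    imp = permutation_importance(full, X, y, n_repeats=5, random_state=seed,
                                 n_jobs=1).importances_mean
    keep = imp > importance_fraction * imp.max() if imp.max() > 0 else imp >= 0
    selected = tuple(np.asarray(covariate_table.columns)[keep])
    if not selected:
        selected = tuple(covariate_table.columns)
    forest = fit(covariate_table[list(selected)].to_numpy(float))
    oob = forest.oob_decision_function_
    valid = ~np.isnan(oob[:, 1])
    oob_auc = float(roc_auc_score(y[valid], oob[valid, 1])) if valid.any() else float("nan")
    return FailureModel(forest=forest, selected_covariates=selected,
                        n_trees=n_trees, oob_auc=oob_auc)


def failure_alert(model: FailureModel, covariates: dict | pd.Series) -> float:
    """1 minus the fraction of the forest's trees voting registration success."""
    row = dict(covariates)
    missing = [c for c in model.selected_covariates if c not in row
               or row[c] is None or not np.isfinite(float(row[c]))]
    if missing:
        raise InputError(f"missing covariate(s): {missing}")
    x = np.array([[float(row[c]) for c in model.selected_covariates]])
    votes_success = 0
    for tree in model.forest.estimators_:
        votes_success += int(model.forest.classes_[
            int(np.argmax(tree.predict_proba(x)[0]))] == 1)
    return 1.0 - votes_success / len(model.forest.estimators_)


def evaluate_contingency(outcomes_a, outcomes_b) -> ContingencySummary:
    """Cross-tabulate two equal-length boolean success lists."""
    a = np.asarray(outcomes_a, bool)
    b = np.asarray(outcomes_b, bool)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise InputError("outcome lists must be equal-length, nonempty 1-D")
    cells = np.array([[(a & b).sum(), (a & ~b).sum()],
                      [(~a & b).sum(), (~a & ~b).sum()]])
    return ContingencySummary(cells=cells)


def auc_score(scores, labels, extra=None) -> float:
    """AUC of a plain maximum-likelihood logistic fit of failure on score(s).

    With one monotone regressor this equals the rank AUC of the raw
    scores; ``extra`` adds a second regressor (e.g. overlapdiff).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool).astype(int)
    if labels.all() or not labels.any():
        raise UndefinedValueError("both classes required for an AUC")
    X = scores[:, None] if scores.ndim == 1 else scores
    if extra is not None:
        X = np.column_stack([X, np.asarray(extra, float)])
    if X.shape[1] == 1:
        # a univariate logistic fit is a monotone transform of the score,
        # so its probability AUC equals the rank AUC of the raw scores
        return float(roc_auc_score(labels, X[:, 0]))
    Xc = sm.add_constant(X, has_constant="add")
    try:
        import warnings
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separable classes are an expected, benign case here
            warnings.simplefilter("ignore")
            fit = sm.Logit(labels, Xc).fit(disp=0, maxiter=200)
            probs = fit.predict(Xc)
        if not np.all(np.isfinite(probs)):
            raise ValueError
    except Exception:
        # perfect separation: the ML fit diverges but its limiting ranking
        # is the dominant score's ranking
        probs = X[:, 0]
    return float(roc_auc_score(labels, probs))


def make_synthetic_covariates(n_rows: int = 500, failure_rate: float = 0.3,
                              shift_sd: float = 3.0, seed: int = 0
                              ) -> tuple[pd.DataFrame, np.ndarray]:
    """Synthetic affine-covariate table with planted failure structure.

    Successes draw from distributions mimicking well-registered pairs
    (overlap near 50%, small rotation/skew); failures shift overlap_pct
    (and, more weakly, similarity and NMI) by ``shift_sd`` standard
    deviations.  Returns (table, success_labels).
    """
    rng = np.random.default_rng(seed)
    n_fail = int(round(n_rows * failure_rate))
    n_succ = n_rows - n_fail
    labels = np.array([True] * n_succ + [False] * n_fail)

    def block(n: int, fail: bool) -> pd.DataFrame:
        shift = shift_sd if fail else 0.0
        return pd.DataFrame({
            "similarity": rng.normal(1.25 - 0.04 * shift, 0.04, n),
            "nmi": rng.normal(1.15 - 0.03 * shift, 0.03, n),
            "overlap_pct": rng.normal(0.50 - 0.06 * shift, 0.06, n).clip(0, 1),
            "tx": rng.normal(384 + 15 * shift, 15, n),
            "ty": rng.normal(0, 10, n),
            "rotation": rng.normal(0, 1.5, n),
            "skew": rng.normal(0.002 * shift, 0.002, n),
        })

    table = pd.concat([block(n_succ, False), block(n_fail, True)],
                      ignore_index=True)[list(ALL_COVARIATES)]
    return table, labels


def make_synthetic_evaluation(n_rows: int = 400, failure_rate: float = 0.3,
                              shift_sd: float = 3.0, seed: int = 0
                              ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Evaluation set for the self-awareness analysis.

    Same covariate model as :func:`make_synthetic_covariates` plus an
    ``overlapdiff`` column (percentage points): when both methods agree
    the difference is small, while a failure of either inflates it.
    Returns (table, success_labels, overlapdiff).
    """
    table, labels = make_synthetic_covariates(n_rows=n_rows,
                                              failure_rate=failure_rate,
                                              shift_sd=shift_sd, seed=seed)
    rng = np.random.default_rng(seed + 1)
    diff = np.where(labels,
                    np.abs(rng.normal(1.5, 1.5, n_rows)),
                    np.abs(rng.normal(9.0, 6.0, n_rows)))
    return table, labels, diff
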