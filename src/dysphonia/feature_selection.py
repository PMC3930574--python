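"""Sequential forward selection (SFS) of vocal measures.

A greedy wrapper search: starting from the empty set, at each step the
candidate measure that most improves the wrapper criterion is appended. The
wrapper is a binary logistic regression and the criterion is stratified
k-fold cross-validated accuracy, which guards against the wrapper overfitting
a table of ~200 records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .data_io import FeatureTable, canonical_measure_name

MAX_IRLS_ITER = 100
IRLS_TOL = 1e-8
RIDGE_FALLBACK = 1e-6


class LogisticFitError(RuntimeError):
    pass


@dataclass
class LogisticModel:
    """Fitted binary logistic regression of PD status on chosen measures."""

    measures: list[str]
    coefficients: np.ndarray  # per included measure
    intercept: float
    converged: bool
    separation_flag: bool = False

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = np.asarray(X) @ self.coefficients + self.intercept
        return 1.0 / (1.0 + np.exp(-eta))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


@dataclass
class SFSResult:
    selected: list[str]
    criterion_trace: list[tuple[int, dict[str, float], float]] = field(default_factory=list)
    # each entry: (step, {candidate -> criterion}, best criterion value)


def fit_logistic(table: FeatureTable, measures: list[str]) -> LogisticModel:
    """Maximum-likelihood logistic fit (Newton/IRLS) of label on the measures.

    When (quasi-)separation prevents the MLE from existing, a tiny ridge
    penalty is applied instead and the model is flagged.
    """
    names = [canonical_measure_name(m) for m in measures]
    X = table.matrix(names) if names else np.empty((len(table), 0))
    y = table.y()
    if len(np.unique(y)) < 2:
        raise LogisticFitError("both classes required for a logistic fit")
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=MAX_IRLS_ITER, tol=IRLS_TOL)
            converged = bool(res.mle_retvals.get("converged", False))
            params = np.asarray(res.params, dtype=float)
            separated = not np.all(np.isfinite(params)) or np.abs(params).max() > 1e6
        except Exception:
            converged, separated, params = False, True, None
    if converged and not separated:
        return LogisticModel(names, params[1:], float(params[0]), True, False)
    # separation / non-convergence: tiny ridge keeps coefficients finite
    lr = LogisticRegression(C=1.0 / RIDGE_FALLBACK, solver="lbfgs",
                            max_iter=5000, tol=IRLS_TOL)
    lr.fit(Xc[:, 1:] if names else np.zeros((len(y), 1)), y)
    coef = lr.coef_.ravel() if names else np.zeros(0)
    if not np.all(np.isfinite(coef)):
        raise LogisticFitError("logistic fit failed to converge even with ridge fallback")
    return LogisticModel(names, coef, float(lr.intercept_[0]), True, True)


def _cv_accuracy(X: np.ndarray, y: np.ndarray, folds: int, seed: int) -> float:
    """Stratified k-fold CV accuracy of a near-unpenalized logistic wrapper."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in skf.split(X, y):
        lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lr.fit(X[tr], y[tr])
        correct += int((lr.predict(X[te]) == y[te]).sum())
    return correct / len(y)


def sfs_select(table: FeatureTable, max_features: int = 4, folds: int = 5,
               seed: int = 0, candidates: list[str] | None = None) -> SFSResult:
    """Greedy forward selection maximizing logistic CV accuracy.

    At each step every remaining candidate is evaluated together with the
    already-selected set; the best is appended. Stops at ``max_features`` or
    as soon as no candidate improves the criterion. Ties break by measure
    column order. Deterministic given ``seed``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    names = [canonical_measure_name(m) for m in (candidates or table.measure_names)]
    if max_features > len(names):
        raise ValueError("max_features exceeds the number of candidate measures")
    y = table.y()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for feature selection")
    cols = {m: table.matrix([m]).ravel() for m in names}

    selected: list[str] = []
    trace: list[tuple[int, dict[str, float], float]] = []
    best_so_far = -np.inf
    for step in range(max_features):
        scores: dict[str, float] = {}
        for m in names:
            if m in selected:
                continue
            X = np.column_stack([cols[f] for f in selected + [m]])
            scores[m] = _cv_accuracy(X, y, folds, seed)
        # argmax with ties broken by column order
        best_val = max(scores.values())
        best_m = next(m for m in names if m in scores and scores[m] == best_val)
        trace.append((step, scores, best_val))
        if best_val <= best_so_far:
            trace.pop()
            break
        selected.append(best_m)
        best_so_far = best_val
    return SFSResult(selected, trace)
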