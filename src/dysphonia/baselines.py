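"""Comparison classifiers on the 2-D score plane: Fisher's linear
discriminant and a soft-margin RBF-kernel support vector machine.

Both consume the same bivariate scores as the MAP classifier so the
comparison isolates the decision rule rather than the feature space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data_io import LABEL_CO, LABEL_PD

SVM_GRID_DEFAULT = tuple(2.0 ** k for k in range(-5, 6))


@dataclass
class FLDAModel:
    """Fisher's linear discriminant: w maximizes between- over within-class scatter."""

    w: np.ndarray  # (2,)
    threshold: float
    S_W: np.ndarray
    S_B: np.ndarray

    def decision(self, Z: np.ndarray) -> np.ndarray:
        """Signed projection w.z - threshold; larger = more PD-like."""
        return np.atleast_2d(Z) @ self.w - self.threshold

    def predict(self, Z: np.ndarray) -> np.ndarray:
        return np.where(self.decision(Z) >= 0, LABEL_PD, LABEL_CO)


def fit_flda(scores: np.ndarray, labels: np.ndarray, regularize: bool = False) -> FLDAModel:
    """Closed-form FLDA: w proportional to S_W^-1 (m_PD - m_CO), threshold at the
    midpoint of projected class means (classify PD iff w.z >= threshold)."""
    Z = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    groups = {lab: Z[labels == lab] for lab in (LABEL_CO, LABEL_PD)}
    if any(len(g) == 0 for g in groups.values()):
        raise ValueError("both classes must be present")
    means = {lab: g.mean(axis=0) for lab, g in groups.items()}
    S_W = np.zeros((Z.shape[1], Z.shape[1]))
    for lab, g in groups.items():
        centered = g - means[lab]
        S_W += centered.T @ centered
    dm = (means[LABEL_PD] - means[LABEL_CO])[:, None]
    S_B = dm @ dm.T
    if regularize:
        S_W = S_W + 1e-8 * np.eye(S_W.shape[0])
    try:
        w = np.linalg.solve(S_W, dm.ravel())
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular within-class scatter; refit with regularize=True") from exc
    if not np.all(np.isfinite(w)):
        raise np.linalg.LinAlgError(
            "singular within-class scatter; refit with regularize=True")
    threshold = float(w @ (means[LABEL_PD] + means[LABEL_CO]) / 2.0)
    return FLDAModel(w, threshold, S_W, S_B)


@dataclass
class SVMModel:
    """Soft-margin RBF SVM; wraps the fitted dual solution."""

    svc: SVC
    C: float
    gamma: float

    @property
    def support_vectors(self) -> np.ndarray:
        return self.svc.support_vectors_

    @property
    def dual_coef(self) -> np.ndarray:
        return self.svc.dual_coef_.ravel()

    @property
    def bias(self) -> float:
        return float(self.svc.intercept_[0])

    def decision(self, Z: np.ndarray) -> np.ndarray:
        """Signed margin, oriented so larger = more PD-like."""
        return self.svc.decision_function(np.atleast_2d(Z))

    def predict(self, Z: np.ndarray) -> np.ndarray:
        return np.where(self.decision(Z) >= 0, LABEL_PD, LABEL_CO)


def fit_svm(scores: np.ndarray, labels: np.ndarray, C: float = 1.0,
            gamma: float = 1.0, tol: float = 1e-3) -> SVMModel:
    """Solve the soft-margin RBF dual (box constraint 0 <= alpha_i <= C)."""
    if C <= 0 or gamma <= 0:
        raise ValueError("C and gamma must be positive")
    Z = np.asarray(scores, dtype=float)
    y = (np.asarray(labels) == LABEL_PD).astype(int)
    svc = SVC(C=C, gamma=gamma, kernel="rbf", tol=tol)
    svc.fit(Z, y)
    if svc.fit_status_ != 0:
        raise RuntimeError(f"SVM solver did not converge (status {svc.fit_status_})")
    return SVMModel(svc, C, gamma)


def kkt_residual(model: SVMModel, scores: np.ndarray, labels: np.ndarray) -> float:
    """Maximum violation of the KKT optimality conditions of the dual.

    For each training point with signed label t and margin f: alpha = 0
    requires t*f >= 1, 0 < alpha < C requires t*f = 1, alpha = C requires
    t*f <= 1. Returns the largest violation magnitude.
    """
    Z = np.asarray(scores, dtype=float)
    t = np.where(np.asarray(labels) == LABEL_PD, 1.0, -1.0)
    f = model.decision(Z)
    alpha = np.zeros(len(Z))
    alpha[model.svc.support_] = np.abs(model.dual_coef)
    tf = t * f
    resid = np.zeros(len(Z))
    free = (alpha > 1e-9) & (alpha < model.C - 1e-9)
    resid[alpha <= 1e-9] = np.maximum(0.0, 1.0 - tf[alpha <= 1e-9])
    resid[free] = np.abs(1.0 - tf[free])
    atC = alpha >= model.C - 1e-9
    resid[atC] = np.maximum(0.0, tf[atC] - 1.0)
    return float(resid.max())


def gamma_scale(scores: np.ndarray) -> float:
    """Scale heuristic 1 / (n_features * Var(Z)) anchoring the RBF width.

    KPCA scores inherit the arbitrary magnitude of the raw polynomial kernel,
    so absolute gamma values are meaningless; grid entries are multipliers of
    this data-driven scale.
    """
    Z = np.asarray(scores, dtype=float)
    v = Z.var()
    if v <= 0:
        raise ValueError("cannot scale gamma on zero-variance scores")
    return 1.0 / (Z.shape[1] * v)


def tune_svm(scores: np.ndarray, labels: np.ndarray,
             C_grid=SVM_GRID_DEFAULT, gamma_grid=SVM_GRID_DEFAULT,
             folds: int = 5, seed: int = 0, scale_gamma: bool = True
             ) -> tuple[float, float]:
    """Inner stratified-CV accuracy argmax over (C, gamma); ties break toward
    the smallest C then the smallest gamma. Seed-reproducible.

    With ``scale_gamma`` (default) the gamma grid entries are multipliers of
    the :func:`gamma_scale` heuristic; the returned gamma is absolute.
    """
    C_grid, gamma_grid = sorted(C_grid), sorted(gamma_grid)
    if not C_grid or not gamma_grid:
        raise ValueError("grids must be non-empty")
    Z = np.asarray(scores, dtype=float)
    if scale_gamma:
        g0 = gamma_scale(Z)
        gamma_grid = [g * g0 for g in gamma_grid]
    y = (np.asarray(labels) == LABEL_PD).astype(int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Z, y))
    best = None
    for C, g in itertools.product(C_grid, gamma_grid):
        correct = 0
        for tr, te in splits:
            svc = SVC(C=C, gamma=g, kernel="rbf")
            svc.fit(Z[tr], y[tr])
            correct += int((svc.predict(Z[te]) == y[te]).sum())
        acc = correct / len(y)
        if best is None or acc > best[0]:
            best = (acc, C, g)
    return float(best[1]), float(best[2])
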