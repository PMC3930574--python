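"""Polynomial-kernel principal component analysis onto a 2-D score plane.

KPCA performs ordinary PCA in the feature space induced by the kernel
k(x, y) = (x.y + c)^d: the n-by-n kernel matrix is double-centered,
eigendecomposed, and the top two eigenpairs define dual coefficient vectors
that map any measure vector to a bivariate score z = (z1, z2). Out-of-sample
projection applies the stored centering statistics to the cross-kernel row.

The kernel parameters (d, c) are chosen on a grid by maximizing the
separation of the healthy-control and PD score centroids. Because the raw
(unnormalized) vocal measures make kernel magnitudes grow with d, the
separation is measured scale-free: centroid distance divided by the pooled
within-class score spread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .data_io import LABEL_CO, LABEL_PD, FeatureTable, canonical_measure_name


class KPCADegeneracyError(RuntimeError):
    pass


@dataclass(frozen=True)
class KernelParams:
    """Polynomial kernel parameters: degree d >= 1 and intercept c >= 0."""

    degree: int
    intercept: float

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if self.intercept < 0:
            raise ValueError("intercept must be >= 0")


def polynomial_kernel(x: np.ndarray, y: np.ndarray, params: KernelParams) -> float:
    """k(x, y) = (x.y + c)^d."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    return float((x @ y + params.intercept) ** params.degree)


def _kernel_matrix(X: np.ndarray, Y: np.ndarray, params: KernelParams) -> np.ndarray:
    return (X @ Y.T + params.intercept) ** params.degree


@dataclass
class KPCAModel:
    training_vectors: np.ndarray  # (n, p)
    params: KernelParams
    kernel_row_means: np.ndarray  # column means of the training kernel matrix
    kernel_grand_mean: float
    eigenvalues: np.ndarray  # (2,), lambda1 >= lambda2 > 0
    alphas: np.ndarray  # (n, 2) scaled dual coefficients
    signs: np.ndarray  # (2,) component sign convention applied
    training_scores: np.ndarray  # (n, 2)

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        """Project measure vectors onto the 2-D KPCA score plane."""
        V = np.atleast_2d(np.asarray(vectors, dtype=float))
        if V.shape[1] != self.training_vectors.shape[1]:
            raise ValueError("vector length does not match training vectors")
        K = _kernel_matrix(V, self.training_vectors, self.params)
        Kc = (K - K.mean(axis=1, keepdims=True)
              - self.kernel_row_means[None, :] + self.kernel_grand_mean)
        scores = Kc @ self.alphas
        return scores if np.asarray(vectors).ndim == 2 else scores[0]


def fit_kpca(vectors: np.ndarray, params: KernelParams, n_components: int = 2,
             labels: np.ndarray | None = None) -> KPCAModel:
    """Fit KPCA on training measure vectors, keeping the top eigenpairs.

    Dual vectors follow the unit-norm-in-feature-space convention, so each
    component's training-score variance equals eigenvalue / (n - 1).

    Component signs are fixed so that the PD-minus-CO centroid difference
    along each component is >= 0 when ``labels`` is given; without labels the
    training score of largest magnitude is made positive.
    """
    X = np.asarray(vectors, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 training vectors")
    K = _kernel_matrix(X, X, params)
    if np.abs(K - K.T).max() > 1e-8 * max(1.0, np.abs(K).max()):
        raise ValueError("kernel matrix not numerically symmetric")
    K = (K + K.T) / 2.0
    row_means = K.mean(axis=0)
    grand = float(K.mean())
    Kc = K - row_means[None, :] - row_means[:, None] + grand
    evals, evecs = eigh(Kc, subset_by_index=(n - n_components, n - 1))
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # strict positivity: zero/negative eigenvalues mean the centered kernel
    # cannot support the requested number of components
    tol = max(np.abs(Kc).max(), 1.0) * 1e-12
    if np.any(evals <= tol):
        raise KPCADegeneracyError(
            f"top-{n_components} eigenvalues not strictly positive for "
            f"d={params.degree}, c={params.intercept}")
    alphas = evecs / np.sqrt(evals)[None, :]  # feature-space unit norm
    scores = Kc @ alphas  # = sqrt(lambda_k) * u_k
    if labels is not None:
        labels = np.asarray(labels)
        diff = scores[labels == LABEL_PD].mean(axis=0) - scores[labels == LABEL_CO].mean(axis=0)
        signs = np.where(diff >= 0, 1.0, -1.0)
    else:
        signs = np.sign(scores[np.abs(scores).argmax(axis=0), range(n_components)])
        signs[signs == 0] = 1.0
    alphas = alphas * signs[None, :]
    scores = scores * signs[None, :]
    return KPCAModel(X, params, row_means, grand, evals, alphas, signs, scores)


def centroid_separation(scores: np.ndarray, labels: np.ndarray) -> float:
    """Scale-free class separation of 2-D scores.

    Euclidean distance between class centroids divided by the square root of
    the trace of the pooled within-class covariance.
    """
    labels = np.asarray(labels)
    co, pd_ = scores[labels == LABEL_CO], scores[labels == LABEL_PD]
    d = np.linalg.norm(pd_.mean(axis=0) - co.mean(axis=0))
    pooled = 0.0
    for grp in (co, pd_):
        if len(grp) > 1:
            pooled += np.trace(np.cov(grp, rowvar=False)) * (len(grp) - 1)
    denom = np.sqrt(pooled / max(len(scores) - 2, 1))
    return float(d / denom) if denom > 0 else np.inf


def select_kernel_params(table: FeatureTable, measures: list[str],
                         grid_d=range(1, 11), grid_c=range(1, 11)
                         ) -> tuple[KernelParams, pd.DataFrame]:
    """Grid search (d, c) maximizing class-centroid separation of the scores.

    Ties break toward smaller d, then smaller c. Degenerate grid points are
    recorded with NaN criterion. Returns the winning parameters and the full
    criterion table for audit.
    """
    grid_d, grid_c = list(grid_d), list(grid_c)
    if not grid_d or not grid_c:
        raise ValueError("parameter grids must be non-empty")
    names = [canonical_measure_name(m) for m in measures]
    X = table.matrix(names)
    labels = table.labels
    rows = []
    best: tuple[float, int, float] | None = None
    for d in grid_d:
        for c in grid_c:
            params = KernelParams(int(d), float(c))
            try:
                model = fit_kpca(X, params, labels=labels)
                crit = centroid_separation(model.training_scores, labels)
            except KPCADegeneracyError:
                crit = np.nan
            rows.append({"d": int(d), "c": float(c), "criterion": crit})
            if np.isfinite(crit) and (best is None or crit > best[0]):
                best = (crit, int(d), float(c))
    if best is None:
        raise KPCADegeneracyError("all grid points degenerate")
    crit_table = pd.DataFrame(rows)
    return KernelParams(best[1], best[2]), crit_table
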