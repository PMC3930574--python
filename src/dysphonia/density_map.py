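"""Per-class Parzen-window density estimation on the 2-D score plane and
maximum a posteriori (MAP) classification.

Each class-conditional density is the average of bivariate Gaussian kernels
centered on that class's training scores. All kernels share one diagonal
covariance h * diag(sigma1^2, sigma2^2), where sigma1^2, sigma2^2 are the
variances of the two score components over all training records pooled and
h in (0, 1] scales the kernel spread. Posteriors follow Bayes' rule from the
class-conditional densities and class priors; densities are computed in log
space throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .data_io import LABEL_CO, LABEL_PD

H_GRID_DEFAULT = np.round(np.arange(0.01, 1.0 + 1e-9, 0.01), 2)


@dataclass
class KDEModel:
    """Fitted two-class Parzen model on the 2-D score plane."""

    class_centers: dict[str, np.ndarray]  # label -> (N_w, 2) training scores
    variances: np.ndarray  # (sigma1^2, sigma2^2) over pooled training scores
    h: float
    priors: dict[str, float]

    def __post_init__(self) -> None:
        if not (0.0 < self.h <= 1.0):
            raise ValueError("scaling factor h must be in (0, 1]")
        if np.any(self.variances <= 0):
            raise ValueError("component variances must be positive")
        total = sum(self.priors.values())
        if abs(total - 1.0) > 1e-9 or any(p <= 0 for p in self.priors.values()):
            raise ValueError("priors must be positive and sum to 1")
        for lab, centers in self.class_centers.items():
            if len(centers) < 1:
                raise ValueError(f"class {lab} has no training scores")

    @property
    def covariance(self) -> np.ndarray:
        return self.h * np.diag(self.variances)


def fit_kde(scores: np.ndarray, labels: np.ndarray, h: float,
            priors: str | dict[str, float] = "empirical") -> KDEModel:
    """Fit the per-class Parzen model.

    ``priors`` may be "empirical" (class frequencies), "equal", or an
    explicit mapping label -> prior.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    centers = {lab: scores[labels == lab] for lab in (LABEL_CO, LABEL_PD)}
    if any(len(v) == 0 for v in centers.values()):
        raise ValueError("both classes must be present")
    variances = scores.var(axis=0, ddof=1)
    if np.any(variances <= 0):
        raise ValueError("zero variance in a score component")
    if priors == "empirical":
        pri = {lab: len(v) / len(scores) for lab, v in centers.items()}
    elif priors == "equal":
        pri = {LABEL_CO: 0.5, LABEL_PD: 0.5}
    else:
        pri = dict(priors)
    return KDEModel(centers, variances, float(h), pri)


def log_density(model: KDEModel, label: str, points: np.ndarray) -> np.ndarray:
    """Log class-conditional density log p(z | label) at the given points."""
    Z = np.atleast_2d(np.asarray(points, dtype=float))
    centers = model.class_centers[label]
    var = model.h * model.variances  # diagonal of the shared covariance
    log_norm = -np.log(2 * np.pi) - 0.5 * np.sum(np.log(var))
    # (m, N_w) squared Mahalanobis distances under the diagonal covariance
    d2 = (((Z[:, None, :] - centers[None, :, :]) ** 2) / var[None, None, :]).sum(axis=2)
    out = logsumexp(-0.5 * d2, axis=1) + log_norm - np.log(len(centers))
    return out if np.asarray(points).ndim == 2 else out[0]


def density(model: KDEModel, label: str, points: np.ndarray) -> np.ndarray:
    """Class-conditional Parzen density p(z | label); strictly positive."""
    return np.exp(log_density(model, label, points))


@dataclass
class PosteriorResult:
    densities: dict[str, float]
    posteriors: dict[str, float]
    predicted: str
    underflow: bool = False


def posterior(model: KDEModel, point: np.ndarray) -> PosteriorResult:
    """Bayes posterior P(class | z) and the MAP label (ties favor PD)."""
    res = posterior_batch(model, np.atleast_2d(np.asarray(point, dtype=float)))
    return res[0]


def posterior_batch(model: KDEModel, points: np.ndarray) -> list[PosteriorResult]:
    Z = np.atleast_2d(np.asarray(points, dtype=float))
    labs = (LABEL_CO, LABEL_PD)
    logd = np.column_stack([log_density(model, lab, Z) for lab in labs])
    logpri = np.log([model.priors[lab] for lab in labs])
    logpost = logd + logpri[None, :]
    norm = logsumexp(logpost, axis=1, keepdims=True)
    underflow = ~np.isfinite(norm.ravel())
    post = np.exp(logpost - np.where(np.isfinite(norm), norm, 0.0))
    results = []
    for i in range(len(Z)):
        if underflow[i]:
            p = {lab: model.priors[lab] for lab in labs}
            pred = LABEL_PD if p[LABEL_PD] >= 0.5 else LABEL_CO
        else:
            p = {lab: float(post[i, j]) for j, lab in enumerate(labs)}
            # tie -> PD, decided on the log scale to avoid rounding at 0.5
            pred = LABEL_PD if logpost[i, 1] >= logpost[i, 0] else LABEL_CO
        results.append(PosteriorResult(
            {lab: float(np.exp(logd[i, j])) for j, lab in enumerate(labs)},
            p, pred, bool(underflow[i])))
    return results


def pd_posterior(model: KDEModel, points: np.ndarray) -> np.ndarray:
    """P(PD | z) for an array of points; the MAP decision score."""
    return np.array([r.posteriors[LABEL_PD] for r in posterior_batch(model, points)])


@dataclass
class BandwidthSearch:
    h: float
    trace: list[tuple[float, float]] = field(default_factory=list)  # (h, criterion)


def select_bandwidth(scores: np.ndarray, labels: np.ndarray,
                     grid: np.ndarray = H_GRID_DEFAULT) -> BandwidthSearch:
    """Pick h on the grid by leave-one-out log-likelihood.

    Each training score is held out and evaluated under its own class's
    Parzen density built from the remaining scores of that class; the h
    maximizing the summed log-likelihood wins (ties -> smaller h).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("grid must be non-empty with positive values")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    variances = scores.var(axis=0, ddof=1)
    if np.any(variances <= 0):
        raise ValueError("zero variance in a score component")
    # precompute per-class squared component differences once
    class_d2: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for lab in (LABEL_CO, LABEL_PD):
        Zw = scores[labels == lab]
        if len(Zw) < 2:
            raise ValueError(f"class {lab} needs >= 2 scores for leave-one-out")
        diff2 = (Zw[:, None, :] - Zw[None, :, :]) ** 2  # (N, N, 2)
        class_d2[lab] = (diff2[..., 0], diff2[..., 1])
    trace = []
    best_h, best_ll = None, -np.inf
    for h in grid:
        var = h * variances
        log_norm = -np.log(2 * np.pi) - 0.5 * np.sum(np.log(var))
        ll = 0.0
        for lab, (dx2, dy2) in class_d2.items():
            N = dx2.shape[0]
            expo = -0.5 * (dx2 / var[0] + dy2 / var[1])
            np.fill_diagonal(expo, -np.inf)  # exclude self
            ll += float(np.sum(logsumexp(expo, axis=1) + log_norm - np.log(N - 1)))
        trace.append((float(h), ll))
        if np.isfinite(ll) and ll > best_ll:
            best_h, best_ll = float(h), ll
    if best_h is None:
        raise RuntimeError("leave-one-out criterion is -inf on the whole grid")
    return BandwidthSearch(best_h, trace)
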