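"""Measure-measure Pearson correlation and collinearity filtering.

Several of the MDVP perturbation measures quantify near-identical signal
properties (e.g. the shimmer family), so the raw table carries heavily
redundant columns; pairs with |r| above a threshold are pruned down to a
single representative before feature selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import FeatureTable


@dataclass
class CorrelationMatrix:
    measure_names: list[str]
    values: np.ndarray  # symmetric, unit diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.measure_names),) * 2:
            raise ValueError("correlation matrix shape does not match measure names")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite correlation entries")
        if np.abs(v - v.T).max() > 1e-12:
            raise ValueError("correlation matrix not symmetric")
        self.values = v

    def r(self, a: str, b: str) -> float:
        i, j = self.measure_names.index(a), self.measure_names.index(b)
        return float(self.values[i, j])


def correlation_matrix(table: FeatureTable) -> CorrelationMatrix:
    """Pairwise Pearson correlations over all records, both classes pooled.

    Zero-variance measures cannot carry a correlation; their off-diagonal
    coefficients are set to 0 (with a warning) and the diagonal stays 1.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 records")
    X = table.matrix()
    sd = X.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        names = [m for m, d in zip(table.measure_names, degenerate) if d]
        warnings.warn(f"zero-variance measures {names}: correlations set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R = np.asarray(R, dtype=float)
    R[degenerate, :] = 0.0
    R[:, degenerate] = 0.0
    np.fill_diagonal(R, 1.0)
    R = np.clip(R, -1.0, 1.0)
    R = (R + R.T) / 2.0
    return CorrelationMatrix(list(table.measure_names), R)


def filter_collinear(matrix: CorrelationMatrix, threshold: float = 0.95
                     ) -> tuple[list[str], list[str]]:
    """Greedily remove one member of every measure pair with |r| > threshold.

    Pairs are visited in descending |r| order; within a pair the measure that
    comes later in column order is dropped. Deterministic, and idempotent on
    the retained set.

    Returns ``(retained, removed)`` measure-name lists.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    names = matrix.measure_names
    n = len(names)
    absR = np.abs(matrix.values)
    pairs = [(absR[i, j], i, j) for i in range(n) for j in range(i + 1, n)
             if absR[i, j] > threshold]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    removed: set[int] = set()
    for _, i, j in pairs:
        if i in removed or j in removed:
            continue
        removed.add(max(i, j))  # drop the later measure in column order
    retained = [names[k] for k in range(n) if k not in removed]
    dropped = [names[k] for k in range(n) if k in removed]
    return retained, dropped
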