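"""Analytic hierarchy process: criterion weights from pairwise comparisons.

Weights for the four environmental parameters come from the principal
eigenvector of a reciprocal pairwise-comparison matrix (Saaty's 1-9
scale), with the consistency ratio CR = CI / RI as the sanity check
(CI = (lambda_max - n) / (n - 1), RI the standard random index). The
shipped factory parameterization carries fixed default weights; AHP is an
optional route to derive alternatives.
"""

from __future__ import annotations

import numpy as np

#: Saaty random consistency index by matrix order
RANDOM_INDEX = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41,
                9: 1.45, 10: 1.49}

_RECIP_TOL = 1e-9


def _validate(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("pairwise matrix must be square")
    if np.any(m <= 0):
        raise ValueError("pairwise matrix entries must be positive")
    if np.max(np.abs(np.diag(m) - 1.0)) > _RECIP_TOL:
        raise ValueError("pairwise matrix diagonal must be 1")
    if np.max(np.abs(m * m.T - 1.0)) > 1e-6:
        raise ValueError("matrix is not reciprocal (m[j,i] != 1/m[i,j])")
    return m


def weights_from_pairwise(matrix, tol: float = 1e-12, max_iter: int = 10_000):
    """Normalized principal eigenvector and eigenvalue by power iteration.

    Returns ``(weights, lambda_max)`` with weights positive and summing
    to 1. Power iteration converges for these positive matrices by the
    Perron-Frobenius theorem.
    """
    m = _validate(matrix)
    n = m.shape[0]
    v = np.full(n, 1.0 / n)
    lam = float(n)
    for _ in range(max_iter):
        w = m @ v
        lam_new = float(w @ v / (v @ v))
        w /= w.sum()
        if np.max(np.abs(w - v)) < tol and abs(lam_new - lam) < tol:
            v, lam = w, lam_new
            break
        v, lam = w, lam_new
    return v, lam


def consistency_ratio(matrix) -> float:
    """CR = CI / RI; 0 for n <= 2 (two-criterion matrices are always consistent)."""
    m = _validate(matrix)
    n = m.shape[0]
    if n > max(RANDOM_INDEX):
        raise ValueError(f"no random index for n = {n}")
    if n <= 2:
        return 0.0
    _, lam = weights_from_pairwise(m)
    ci = (lam - n) / (n - 1)
    return float(ci / RANDOM_INDEX[n])


def load_pairwise_csv(path, labels: bool = True):
    """Read a pairwise matrix from CSV; first row/column may carry labels."""
    import pandas as pd

    df = pd.read_csv(path, index_col=0 if labels else None, header=0 if labels else None)
    return _validate(df.to_numpy(dtype=float)), list(df.columns) if labels else None
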