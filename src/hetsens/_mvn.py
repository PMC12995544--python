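"""Deterministic multivariate-normal rectangle probabilities.

Genz's separation-of-variables representation turns the orthant/rectangle
probability of a correlated Gaussian vector into an integral over the unit
cube, evaluated here with a scrambled Sobol' rule at a fixed seed so that
repeated calls return identical values (absolute accuracy ~1e-5 for the
dimensions used in practice, K <= 15).
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import qmc

_SEED = 52
_EPS = 1e-14


def _psd_cholesky(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        # repair tiny negative eigenvalues (rank-deficient correlation)
        vals, vecs = np.linalg.eigh(corr)
        vals = np.clip(vals, 1e-10, None)
        fixed = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(fixed))
        fixed = fixed / np.outer(d, d)
        return np.linalg.cholesky(fixed)


def rectangle_probability(upper, corr, n_points: int = 1 << 13) -> float:
    """P(X_k <= upper_k for all k) for X ~ N(0, corr).

    Deterministic quasi-Monte Carlo (Genz separation of variables with a
    seeded scrambled Sobol' rule).
    """
    upper = np.atleast_1d(np.asarray(upper, dtype=float))
    k = upper.size
    if k == 1:
        return float(ndtr(upper[0]))
    L = _psd_cholesky(corr)
    sob = qmc.Sobol(d=k - 1, scramble=True, seed=_SEED)
    w = sob.random(n_points)

    e = np.full(n_points, ndtr(upper[0] / L[0, 0]))
    f = e.copy()
    y = np.empty((n_points, k - 1))
    for i in range(1, k):
        y[:, i - 1] = ndtri(np.clip(w[:, i - 1] * e, _EPS, 1 - _EPS))
        num = upper[i] - y[:, :i] @ L[i, :i]
        e = ndtr(num / L[i, i])
        f *= e
    return float(f.mean())
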