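"""Independent oracles for the quantile engine, kept free of any package
solver code: brute-force grid search for the one-parameter problem and
exhaustive enumeration of interpolating vertex solutions."""

from itertools import combinations

import numpy as np


def check_loss(y, q, tau):
    r = np.asarray(y, float) - np.asarray(q, float)
    return float(np.sum(np.where(r > 0, tau * r, (tau - 1.0) * r)))


def grid_search_quantile(y, tau, resolution=20001):
    """Brute-force minimiser of the check loss over a dense scalar grid."""
    y = np.asarray(y, float)
    grid = np.linspace(y.min(), y.max(), resolution)
    losses = np.array([check_loss(y, np.full_like(y, g), tau) for g in grid])
    return grid[np.argmin(losses)], losses.min()


def vertex_enumeration(X, y, tau):
    """Exhaustive search over all column-subset interpolating solutions.

    A check-loss optimum exists at a 'vertex' beta that interpolates p
    observations exactly; enumerating all p-subsets of rows therefore
    finds the global minimum for small n.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    best_loss = np.inf
    best_beta = None
    for rows in combinations(range(n), p):
        A = X[list(rows)]
        if abs(np.linalg.det(A)) < 1e-12:
            continue
        beta = np.linalg.solve(A, y[list(rows)])
        loss = check_loss(y, X @ beta, tau)
        if loss < best_loss - 1e-12:
            best_loss = loss
            best_beta = beta
    return best_beta, best_loss
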