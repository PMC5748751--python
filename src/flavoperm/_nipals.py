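"""NIPALS partial-least-squares core (single response).

Implements the classical chemometric algorithm on autoscaled data. For a
single y, the NIPALS weight step has a closed form per component:

    w_a = X'y / ||X'y||,  t_a = X w_a,  p_a = X't / t't,  q_a = y't / t't

followed by deflation of X (and y) by the extracted component. Regression
coefficients in the scaled space are B = W (P'W)^-1 q; with as many
components as the rank of X they coincide with the least-squares solution.
"""

from __future__ import annotations

import numpy as np


def nipals_pls1(
    X: np.ndarray, y: np.ndarray, n_components: int, tol: float = 1e-12
) -> tuple[np.ndarray, dict]:
    """Fit PLS1 on already-centered/scaled X (n, k) and y (n,).

    Returns the coefficient vector in the scaled space and a dict of
    loadings/weights/scores for inspection.
    """
    X = np.asarray(X, dtype=float).copy()
    y = np.asarray(y, dtype=float).copy()
    n, k = X.shape
    if not 1 <= n_components <= k:
        raise ValueError(
            f"n_components must be in [1, {k}], got {n_components}"
        )
    if n_components > np.linalg.matrix_rank(X):
        raise ValueError(
            f"n_components={n_components} exceeds rank(X)={np.linalg.matrix_rank(X)}"
        )
    W = np.zeros((k, n_components))
    P = np.zeros((k, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    for a in range(n_components):
        xty = X.T @ y
        norm = np.linalg.norm(xty)
        if norm < tol:
            raise ValueError(f"component {a + 1}: X carries no remaining covariance with y")
        w = xty / norm
        t = X @ w
        tt = t @ t
        if tt < tol:
            raise ValueError(f"component {a + 1}: degenerate score vector")
        p = X.T @ t / tt
        qa = y @ t / tt
        X -= np.outer(t, p)
        y = y - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p, qa, t
    coef = W @ np.linalg.solve(P.T @ W, q)
    return coef, {"weights": W, "loadings": P, "y_loadings": q, "scores": T}
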