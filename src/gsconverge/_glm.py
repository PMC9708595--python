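"""Firth-penalized logistic regression (Jeffreys-prior score correction).

Used as the documented fallback when the ordinary ML logistic fit for a
burden regression fails to converge or separates; the penalty keeps the
estimate finite at the cost of a small shrinkage toward zero.
"""

from __future__ import annotations

import numpy as np


def firth_logit(
    y: np.ndarray,
    X: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Return (beta, standard errors, converged) for a Firth-penalized fit.

    Newton iterations on the penalized score U*(b) = X'(y - p + h (1/2 - p)),
    h the diagonal of the weighted hat matrix; covariance is the inverse
    Fisher information at the solution.
    """
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        XtW = X.T * w
        info = XtW @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            break
        # hat diagonal: h_i = w_i * x_i' (X'WX)^-1 x_i
        h = w * np.einsum("ij,jk,ik->i", X, info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -30.0, 30.0)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    info = (X.T * w) @ X
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se, converged
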