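"""Minimal OLS / logistic solvers for the bootstrap inner loop.

The user-facing fits go through statsmodels (which supplies standard
errors, p-values and robust covariances).  Bootstrap resampling only needs
point estimates, thousands of times over, so these stripped-down numpy
solvers are used there.  They are cross-checked against statsmodels in the
test suite.
"""
from __future__ import annotations

import numpy as np
from scipy.special import expit


def ols_beta(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients of ``y`` on design matrix ``X``."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def logit_fit(
    X: np.ndarray,
    y: np.ndarray,
    beta0: np.ndarray | None = None,
    max_iter: int = 40,
    tol: float = 1e-9,
) -> tuple[np.ndarray, bool]:
    """Newton-Raphson logistic MLE with step halving.

    Returns ``(beta, converged)``.  ``beta0`` allows warm starts from the
    full-data estimate, which brings typical bootstrap replicates down to
    two or three iterations.
    """
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, float).copy()

    def negll(b: np.ndarray) -> float:
        eta = X @ b
        # log(1+exp(eta)) - y*eta, computed stably
        return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)

    f = negll(beta)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, False
        # step halving on the penalised objective
        t = 1.0
        for _ in range(25):
            cand = beta + t * step
            fc = negll(cand)
            if fc <= f + 1e-12:
                break
            t *= 0.5
        else:
            return beta, False
        moved = t * np.max(np.abs(step))
        beta, f = cand, fc
        if moved < tol * (1.0 + np.max(np.abs(beta))):
            return beta, True
    return beta, False
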