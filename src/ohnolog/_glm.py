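"""Newton (IRLS) maximum-likelihood fit of a binary logistic regression.

Kept deliberately small and allocation-light: the permutation test refits
the same model thousands of times with one column changed, so per-fit
overhead dominates the whole analysis.  Warm starts from the unpermuted
solution typically converge in 2-4 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

MAX_ITER = 100
TOL = 1e-8
#: |coefficient| beyond which the fit is flagged as (quasi-)separated.
SEPARATION_BOUND = 1e3


@dataclass
class NewtonFit:
    beta: np.ndarray          # includes leading intercept
    se: np.ndarray
    log_likelihood: float
    converged: bool
    n_iter: int
    message: str = ""


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logit(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = TOL,
    max_iter: int = MAX_ITER,
    beta0: np.ndarray | None = None,
    compute_se: bool = True,
) -> NewtonFit:
    """Fit logit P(y=1) = X @ beta by Newton's method with step-halving.

    ``X`` must already contain the intercept column.  Convergence is
    declared when the largest absolute coefficient change falls below
    ``tol``.  Standard errors come from the inverse observed information;
    divergent coefficients are reported as non-convergence with a
    separation diagnostic rather than raising.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=float)

    eta = X @ beta
    ll = _loglik(eta, y)
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            message = "singular information matrix"
            break
        # step-halving: the likelihood must not decrease
        scale = 1.0
        for _ in range(30):
            beta_new = beta + scale * step
            eta_new = X @ beta_new
            ll_new = _loglik(eta_new, y)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        delta = np.max(np.abs(beta_new - beta))
        beta, eta, ll = beta_new, eta_new, ll_new
        if delta < tol:
            converged = True
            break

    if np.max(np.abs(beta)) > SEPARATION_BOUND:
        converged = False
        message = "divergent coefficients (possible complete separation)"
    elif not converged and not message:
        message = f"no convergence in {max_iter} iterations"

    se = np.full(p, np.nan)
    if compute_se:
        mu = expit(eta)
        w = mu * (1.0 - mu)
        info = (X * w[:, None]).T @ X
        try:
            cov = np.linalg.inv(info)
            d = np.diag(cov)
            se = np.sqrt(np.where(d > 0, d, np.nan))
        except np.linalg.LinAlgError:
            pass
    return NewtonFit(beta, se, ll, converged, it, message)
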