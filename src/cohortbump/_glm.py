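"""Newton/IRLS core for the Poisson log-linear model with offset.

Small, allocation-light solver used by the estimators: the cohort-bump
grid search refits the same model at hundreds of (mu_c, sigma_c) values,
so per-fit overhead matters more than generality here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import qr
from scipy.special import gammaln

__all__ = ["GLMResult", "SingularDesignError", "NonConvergenceWarning",
           "fit_poisson", "poisson_loglik"]

BETA0_WARN = 50.0  # |linear predictor| beyond which exp() is suspect


class SingularDesignError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; names the collinear columns."""


class NonConvergenceWarning(UserWarning):
    pass


@dataclass
class GLMResult:
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    deviance_stat: float  # -2 * loglik, including the log d! constant
    converged: bool
    n_iter: int


def poisson_loglik(eta: np.ndarray, d: np.ndarray) -> float:
    """Sum over cells of ``d*eta - exp(eta) - log(d!)``, with
    ``eta = log z + beta0`` the full linear predictor."""
    with np.errstate(over="ignore"):
        mu = np.exp(eta)
    return float(np.sum(d * eta - mu - gammaln(d + 1.0)))


def check_rank(X: np.ndarray, names: list[str] | None = None) -> None:
    """Raise :class:`SingularDesignError` naming dependent columns."""
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = sorted(piv[rank:])
        labels = [names[j] if names else str(j) for j in bad]
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < "
            f"{X.shape[1]}); collinear column(s): {labels}")


def fit_poisson(X: np.ndarray, d: np.ndarray, offset: np.ndarray, *,
                tol_score: float = 1e-8, tol_deviance: float = 1e-10,
                max_iter: int = 100, check: bool = True,
                names: list[str] | None = None,
                start: np.ndarray | None = None) -> GLMResult:
    """Maximum likelihood for ``d ~ Poisson(exp(offset + X @ beta))``.

    Newton-Raphson with step halving; for the canonical log link the
    Newton update equals iteratively reweighted least squares and the
    observed information equals the expected one.  Convergence when
    ``max |score| < tol_score`` or the relative change in -2*loglik
    falls below ``tol_deviance``.
    """
    X = np.asarray(X, dtype=float)
    d = np.asarray(d, dtype=float)
    offset = np.asarray(offset, dtype=float)
    n, k = X.shape
    if n < k:
        raise SingularDesignError(
            f"{n} cells for {k} parameters: underdetermined")
    if check:
        check_rank(X, names)

    if start is not None:
        beta = np.asarray(start, dtype=float).copy()
    else:
        # feasible deterministic start: intercept at the crude log rate
        beta = np.zeros(k)
        if np.allclose(X[:, 0], 1.0):
            beta[0] = np.log(max(d.sum(), 0.5)) - np.log(
                np.exp(offset).sum())

    eta = offset + X @ beta
    ll = poisson_loglik(eta, d)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = np.exp(eta)
        score = X.T @ (d - mu)
        if np.max(np.abs(score)) < tol_score:
            converged = True
            break
        info = (X.T * mu) @ X
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SingularDesignError(
                f"Fisher information singular at iteration {it}") from exc
        # step halving keeps the likelihood finite and non-decreasing
        step = 1.0
        for _ in range(50):
            eta_new = offset + X @ (beta + step * delta)
            ll_new = poisson_loglik(eta_new, d)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step *= 0.5
        beta = beta + step * delta
        eta = eta_new
        if abs(ll_new - ll) < tol_deviance * (abs(ll) + 1.0) / 2.0:
            ll = ll_new
            converged = True
            break
        ll = ll_new

    beta0 = eta - offset
    if np.max(np.abs(beta0)) > BETA0_WARN:
        j = int(np.argmax(np.abs(beta0)))
        warnings.warn(
            f"|beta0| = {abs(beta0[j]):.1f} > {BETA0_WARN} at cell {j}; "
            "fitted rates may overflow", RuntimeWarning, stacklevel=2)
    if not converged:
        warnings.warn(
            f"Poisson fit did not converge in {max_iter} iterations",
            NonConvergenceWarning, stacklevel=2)

    mu = np.exp(eta)
    info = (X.T * mu) @ X
    cov = np.linalg.inv(info)
    ll = poisson_loglik(eta, d)
    return GLMResult(coef=beta, cov=cov, loglik=ll, deviance_stat=-2.0 * ll,
                     converged=converged, n_iter=it)
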