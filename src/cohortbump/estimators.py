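"""Scikit-learn style estimators for cohort-bump detection.

Two estimators cover the method:

``PoissonBumpRegression``
    Maximum-likelihood fit of the varying-coefficient Poisson model
    ``d ~ Poisson(z * exp(beta0(a, p)))`` with
    ``beta0 = theta' x(a, p) [+ beta_c * phi(p - a; mu_c, sigma_c)]``
    for a *fixed* bump location (or no bump at all).

``CohortBumpDetector``
    Profile-deviance grid search over (mu_c, sigma_c): refits the
    regression at every grid point, picks the minimizer of -2*loglik,
    and classifies the detected cohort effect as local or global.

Both follow sklearn conventions: hyper-parameters in ``__init__``,
fitted attributes with trailing underscores, ``get_params`` /
``set_params`` via ``BaseEstimator``.  ``X`` is an (n, 2) array of
(age, period) cell coordinates, ``y`` the death counts, and the
person-years enter through the ``exposure`` fit parameter (a Poisson
offset, not a sample weight).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from . import _glm
from .basis import BasisSpec, CohortBump, _design, cohort_density

__all__ = ["PoissonBumpRegression", "CohortBumpDetector", "DetectionError"]


class DetectionError(RuntimeError):
    """Grid search failed at every (mu_c, sigma_c) candidate."""


def _validate_Xy(X, y, exposure):
    X = check_array(X, dtype=float, ensure_min_features=2)
    if X.shape[1] != 2:
        raise ValueError(
            f"X must have exactly 2 columns (age, period); got {X.shape[1]}")
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != len(X):
        raise ValueError("X and y have inconsistent lengths")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("y must hold non-negative integer counts")
    if exposure is None:
        z = np.ones(len(y))
    else:
        z = np.asarray(exposure, dtype=float).ravel()
        if len(z) != len(y):
            raise ValueError("exposure and y have inconsistent lengths")
        if np.any(z <= 0) or not np.all(np.isfinite(z)):
            raise ValueError("exposure must be positive and finite")
    return X, y, z


def _resolve_spec(scaling, ages, periods, age_degree, period_degree):
    if isinstance(scaling, BasisSpec):
        return scaling
    if scaling == "standardize":
        return BasisSpec.from_cells(ages, periods, age_degree, period_degree)
    if scaling == "none":
        return BasisSpec(age_degree=age_degree, period_degree=period_degree)
    raise ValueError(
        "scaling must be 'standardize', 'none' or a BasisSpec; "
        f"got {scaling!r}")


class PoissonBumpRegression(BaseEstimator):
    """Varying-coefficient Poisson regression with an optional Gaussian
    cohort bump at a fixed (mu_c, sigma_c).

    Parameters
    ----------
    age_degree, period_degree : int, default 3
        Degrees of the tensor-product polynomial basis in age and
        period (the default gives the 16-term cubic-by-cubic basis).
    mu_c, sigma_c : float or None
        Center (birth year) and width (years, > 0) of the Gaussian
        cohort basis.  Both None fits the no-bump null model.
    scaling : "standardize", "none" or BasisSpec
        Affine rescaling of age and period before building the
        polynomial block.  "standardize" (default) centers and scales
        to the fitted cells; pass a BasisSpec to reuse a fixed scaling.
        The cohort basis always uses raw birth years.
    tol_score, tol_deviance, max_iter
        IRLS convergence controls; convergence is declared when the
        maximal score component falls below ``tol_score`` or the
        relative deviance change falls below ``tol_deviance``.

    Attributes
    ----------
    coef_ : ndarray, shape (m,)
        Polynomial coefficients theta-hat.
    bump_coef_ : float or None
        beta_c-hat (None when fitted without a bump).
    covariance_ : ndarray
        Inverse Fisher information at the optimum, for all m (+1)
        coefficients, bump last.
    deviance_ : float
        -2 * maximized log-likelihood (including the log d! constant).
    converged_ : bool
    n_iter_ : int
    basis_spec_ : BasisSpec
    bump_ : CohortBump or None
    """

    def __init__(self, age_degree: int = 3, period_degree: int = 3,
                 mu_c: float | None = None, sigma_c: float | None = None,
                 scaling="standardize", tol_score: float = 1e-8,
                 tol_deviance: float = 1e-10, max_iter: int = 100):
        self.age_degree = age_degree
        self.period_degree = period_degree
        self.mu_c = mu_c
        self.sigma_c = sigma_c
        self.scaling = scaling
        self.tol_score = tol_score
        self.tol_deviance = tol_deviance
        self.max_iter = max_iter

    def _bump(self) -> CohortBump | None:
        if (self.mu_c is None) != (self.sigma_c is None):
            raise ValueError("mu_c and sigma_c must be set together")
        if self.mu_c is None:
            return None
        return CohortBump(self.mu_c, self.sigma_c)

    def fit(self, X, y, exposure=None):
        X, y, z = _validate_Xy(X, y, exposure)
        ages, periods = X[:, 0], X[:, 1]
        spec = _resolve_spec(self.scaling, ages, periods,
                             self.age_degree, self.period_degree)
        bump = self._bump()
        D = _design(ages, periods, spec, bump)
        names = spec.term_names + (["beta_c"] if bump is not None else [])
        res = _glm.fit_poisson(
            D, y, np.log(z), tol_score=self.tol_score,
            tol_deviance=self.tol_deviance, max_iter=self.max_iter,
            names=names)

        m = spec.n_terms
        self.basis_spec_ = spec
        self.bump_ = bump
        self.coef_ = res.coef[:m]
        self.bump_coef_ = float(res.coef[m]) if bump is not None else None
        self.covariance_ = res.cov
        self.loglik_ = res.loglik
        self.deviance_ = res.deviance_stat
        self.converged_ = res.converged
        self.n_iter_ = res.n_iter
        self.coef_names_ = names
        self.n_features_in_ = 2
        return self

    def _full_coef(self) -> np.ndarray:
        if self.bump_coef_ is None:
            return self.coef_
        return np.append(self.coef_, self.bump_coef_)

    def linear_predictor(self, X) -> np.ndarray:
        """beta0(a, p) on the log-rate scale."""
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        D = _design(X[:, 0], X[:, 1], self.basis_spec_, self.bump_)
        return D @ self._full_coef()

    def predict_rate(self, X) -> np.ndarray:
        """Mortality rate exp(beta0) per person-year."""
        return np.exp(self.linear_predictor(X))

    def predict(self, X, exposure=None) -> np.ndarray:
        """Expected deaths ``z * exp(beta0)``."""
        rate = self.predict_rate(X)
        return rate if exposure is None else rate * np.asarray(exposure)

    def score(self, X, y, exposure=None) -> float:
        """Mean Poisson log-likelihood per cell (higher is better)."""
        X, y, z = _validate_Xy(X, y, exposure)
        eta = np.log(z) + self.linear_predictor(X)
        return _glm.poisson_loglik(eta, y) / len(y)


def _auto_mu_grid(birth_years: np.ndarray, sigma_max: float) -> np.ndarray:
    """Integer birth years covering the observed span trimmed by one
    sigma_max at each end (edge bumps explained by single corner cells
    are not interpretable)."""
    lo = float(birth_years.min()) + sigma_max
    hi = float(birth_years.max()) - sigma_max
    if hi < lo:
        lo = hi = float(np.median(birth_years))
    return np.arange(np.ceil(lo), np.floor(hi) + 1.0)


class CohortBumpDetector(BaseEstimator):
    """Automatic local birth-cohort effect detection by profile-deviance
    grid search over the bump parameters (mu_c, sigma_c).

    For every candidate bump the varying-coefficient Poisson model is
    refitted by maximum likelihood and scored by -2*loglik; the best
    bump is the grid minimizer (ties broken by smallest sigma_c, then
    smallest mu_c, i.e. the most local, earliest explanation).  A
    detected bump is classified *local* when sigma_c is at most
    ``local_threshold`` (default 5%) of the observed birth-year span;
    otherwise the Gaussian column is deemed to be mopping up a global
    cohort trend and no local effect is declared.

    Parameters
    ----------
    age_degree, period_degree : int, default 3
    mu_grid : "auto" or array of birth years
        "auto" uses integer birth years spanning the observed range
        trimmed by the largest candidate sigma_c at each end.
    sigma_grid : "auto" or array of positive widths (years)
        "auto" uses integers 1 .. min(15, span/4).
    local_threshold : float, default 0.05
        Locality rule: local iff sigma_c / birth-span <= threshold.
    scaling, tol_score, tol_deviance, max_iter
        Passed through to the per-gridpoint regression fits.

    Attributes
    ----------
    best_estimator_ : PoissonBumpRegression fitted at the best bump
    null_estimator_ : PoissonBumpRegression fitted without a bump
    mu_c_, sigma_c_ : best bump parameters
    beta_c_, beta_c_se_, beta_c_z_, beta_c_p_ : Wald inference on beta_c
    deviance_, null_deviance_ : -2*loglik of best and no-bump fits
    is_local_, locality_ratio_, birth_span_ : locality classification
    grid_ : DataFrame (mu_c, sigma_c, deviance, converged)
    n_failed_ : number of grid fits that failed or did not converge
    """

    def __init__(self, age_degree: int = 3, period_degree: int = 3,
                 mu_grid="auto", sigma_grid="auto",
                 local_threshold: float = 0.05, scaling="standardize",
                 tol_score: float = 1e-8, tol_deviance: float = 1e-10,
                 max_iter: int = 100):
        self.age_degree = age_degree
        self.period_degree = period_degree
        self.mu_grid = mu_grid
        self.sigma_grid = sigma_grid
        self.local_threshold = local_threshold
        self.scaling = scaling
        self.tol_score = tol_score
        self.tol_deviance = tol_deviance
        self.max_iter = max_iter

    def _grids(self, birth_years: np.ndarray):
        span = float(birth_years.max() - birth_years.min())
        if isinstance(self.sigma_grid, str) and self.sigma_grid == "auto":
            s_hi = int(min(15, max(1, np.floor(span / 4.0))))
            sigmas = np.arange(1.0, s_hi + 1.0)
        else:
            sigmas = np.sort(np.asarray(self.sigma_grid, dtype=float))
            if len(sigmas) == 0 or np.any(sigmas <= 0):
                raise ValueError("sigma_grid must be non-empty and > 0")
        if isinstance(self.mu_grid, str) and self.mu_grid == "auto":
            mus = _auto_mu_grid(birth_years, sigmas.max())
        else:
            mus = np.sort(np.asarray(self.mu_grid, dtype=float))
            if len(mus) == 0:
                raise ValueError("mu_grid must be non-empty")
            lo, hi = birth_years.min(), birth_years.max()
            if np.any(mus < lo) or np.any(mus > hi):
                raise ValueError(
                    f"mu_grid must lie inside the observed birth-year "
                    f"range [{lo}, {hi}]")
        return mus, sigmas

    def fit(self, X, y, exposure=None):
        X, y, z = _validate_Xy(X, y, exposure)
        ages, periods = X[:, 0], X[:, 1]
        birth = periods - ages
        spec = _resolve_spec(self.scaling, ages, periods,
                             self.age_degree, self.period_degree)
        mus, sigmas = self._grids(birth)
        offset = np.log(z)

        # the polynomial block never changes across the grid
        P = _design(ages, periods, spec, None)
        _glm.check_rank(P, spec.term_names)
        null = _glm.fit_poisson(P, y, offset, tol_score=self.tol_score,
                                tol_deviance=self.tol_deviance,
                                max_iter=self.max_iter, check=False)

        rows = []
        best = None  # (deviance, sigma, mu, result)
        n_failed = 0
        start = np.append(null.coef, 0.0)
        # sigma ascending then mu ascending so that keeping the first
        # strict minimum implements the documented tie-break
        for sig in sigmas:
            for mu in mus:
                phi = norm.pdf(birth, loc=mu, scale=sig)
                D = np.column_stack([P, phi])
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("error",
                                              _glm.NonConvergenceWarning)
                        warnings.simplefilter("ignore", RuntimeWarning)
                        res = _glm.fit_poisson(
                            D, y, offset, tol_score=self.tol_score,
                            tol_deviance=self.tol_deviance,
                            max_iter=self.max_iter, check=True,
                            start=start)
                except (np.linalg.LinAlgError, _glm.NonConvergenceWarning):
                    n_failed += 1
                    rows.append((mu, sig, np.nan, False))
                    continue
                rows.append((mu, sig, res.deviance_stat, True))
                if best is None or res.deviance_stat < best[0]:
                    best = (res.deviance_stat, sig, mu, res)

        if best is None:
            raise DetectionError(
                "every grid fit failed; check the design or the grids")
        if n_failed:
            warnings.warn(f"{n_failed} grid fit(s) failed and were "
                          "excluded from the search", UserWarning)

        _, sig_b, mu_b, res_b = best
        m = spec.n_terms
        se = float(np.sqrt(res_b.cov[m, m]))
        beta_c = float(res_b.coef[m])
        zval = beta_c / se
        span = float(birth.max() - birth.min())

        self.basis_spec_ = spec
        self.grid_ = pd.DataFrame(
            rows, columns=["mu_c", "sigma_c", "deviance", "converged"])
        self.n_failed_ = n_failed
        self.mu_c_ = float(mu_b)
        self.sigma_c_ = float(sig_b)
        self.bump_ = CohortBump(self.mu_c_, self.sigma_c_)
        self.beta_c_ = beta_c
        self.beta_c_se_ = se
        self.beta_c_z_ = zval
        self.beta_c_p_ = float(2.0 * norm.sf(abs(zval)))
        self.deviance_ = res_b.deviance_stat
        self.null_deviance_ = null.deviance_stat
        self.birth_span_ = span
        self.locality_ratio_ = self.sigma_c_ / span if span > 0 else np.inf
        self.is_local_ = bool(self.locality_ratio_ <= self.local_threshold)
        self.n_features_in_ = 2

        fitted = PoissonBumpRegression(
            age_degree=self.age_degree, period_degree=self.period_degree,
            mu_c=self.mu_c_, sigma_c=self.sigma_c_, scaling=spec,
            tol_score=self.tol_score, tol_deviance=self.tol_deviance,
            max_iter=self.max_iter)
        fitted.basis_spec_ = spec
        fitted.bump_ = self.bump_
        fitted.coef_ = res_b.coef[:m]
        fitted.bump_coef_ = beta_c
        fitted.covariance_ = res_b.cov
        fitted.loglik_ = res_b.loglik
        fitted.deviance_ = res_b.deviance_stat
        fitted.converged_ = res_b.converged
        fitted.n_iter_ = res_b.n_iter
        fitted.coef_names_ = spec.term_names + ["beta_c"]
        fitted.n_features_in_ = 2
        self.best_estimator_ = fitted

        null_est = PoissonBumpRegression(
            age_degree=self.age_degree, period_degree=self.period_degree,
            scaling=spec, tol_score=self.tol_score,
            tol_deviance=self.tol_deviance, max_iter=self.max_iter)
        null_est.basis_spec_ = spec
        null_est.bump_ = None
        null_est.coef_ = null.coef
        null_est.bump_coef_ = None
        null_est.covariance_ = null.cov
        null_est.loglik_ = null.loglik
        null_est.deviance_ = null.deviance_stat
        null_est.converged_ = null.converged
        null_est.n_iter_ = null.n_iter
        null_est.coef_names_ = spec.term_names
        null_est.n_features_in_ = 2
        self.null_estimator_ = null_est
        return self

    def relative_risk(self, birth_years) -> np.ndarray:
        """Cohort-effect relative risk exp(beta_c * phi(c)) at the given
        birth years; 1 far from mu_c, extreme exp(beta_c/(sigma_c
        sqrt(2 pi))) at c = mu_c."""
        check_is_fitted(self, "beta_c_")
        c = np.asarray(birth_years, dtype=float)
        phi = norm.pdf(c, loc=self.mu_c_, scale=self.sigma_c_)
        return np.exp(self.beta_c_ * phi)

    def predict(self, X, exposure=None) -> np.ndarray:
        check_is_fitted(self, "best_estimator_")
        return self.best_estimator_.predict(X, exposure=exposure)
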