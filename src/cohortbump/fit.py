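"""Maximum-likelihood fitting and Wald inference for a fixed cohort bump.

Thin functional layer over :class:`~cohortbump.estimators.PoissonBumpRegression`
working on :class:`~cohortbump.data.AgePeriodTable` objects, with result
containers that serialize to JSON in the layout of a coefficient table
(name, estimate, SE, z, p).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2, norm

from .basis import BasisSpec, CohortBump, _design
from .data import AgePeriodTable
from .estimators import PoissonBumpRegression

__all__ = ["FitResult", "CoefficientTest", "log_likelihood", "fit_ml",
           "wald_tests", "likelihood_ratio_test", "InferenceError"]


class InferenceError(RuntimeError):
    """Covariance is numerically singular; Wald inference unavailable."""


@dataclass
class CoefficientTest:
    """Wald test of a single coefficient against zero."""

    name: str
    estimate: float
    std_error: float
    z_value: float
    p_value: float


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit.

    ``deviance_stat`` is -2 times the maximized log-likelihood,
    including the log d! constant, so it is an absolute goodness-of-fit
    index; differences of it between models on the same data are the
    usual likelihood-ratio statistics.
    """

    theta: np.ndarray
    beta_c: float | None
    covariance: np.ndarray
    deviance_stat: float
    converged: bool
    n_iter: int
    bump: CohortBump | None
    spec: BasisSpec

    @property
    def coef(self) -> np.ndarray:
        if self.beta_c is None:
            return self.theta
        return np.append(self.theta, self.beta_c)

    @property
    def coef_names(self) -> list[str]:
        names = self.spec.term_names
        return names + ["beta_c"] if self.beta_c is not None else names

    def to_dict(self) -> dict:
        rows = [{"name": t.name, "estimate": t.estimate,
                 "std_error": t.std_error, "z_value": t.z_value,
                 "p_value": t.p_value} for t in wald_tests(self)]
        return {
            "coefficients": rows,
            "deviance": self.deviance_stat,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "basis_spec": self.spec.to_dict(),
            "bump": self.bump.to_dict() if self.bump else None,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def log_likelihood(theta, beta_c, table: AgePeriodTable,
                   spec: BasisSpec, bump: CohortBump | None = None) -> float:
    """Poisson log-likelihood sum_j [d_j (log z_j + beta0_j) -
    z_j exp(beta0_j) - log d_j!] at the given coefficients."""
    X = _design(table.ages, table.periods, spec, bump)
    coef = np.asarray(theta, dtype=float)
    if bump is not None:
        if beta_c is None:
            raise ValueError("beta_c required when a bump is given")
        coef = np.append(coef, beta_c)
    if coef.shape[0] != X.shape[1]:
        raise ValueError(
            f"coefficient length {coef.shape[0]} != design width {X.shape[1]}")
    beta0 = X @ coef
    big = np.abs(beta0) > 50.0
    if big.any():
        j = int(np.flatnonzero(big)[0])
        raise OverflowError(
            f"|beta0| = {abs(beta0[j]):.1f} > 50 at cell (age="
            f"{table.ages[j]}, period={table.periods[j]})")
    d = table.deaths.astype(float)
    z = table.person_years
    eta = np.log(z) + beta0
    return float(np.sum(d * eta - np.exp(eta) - gammaln(d + 1.0)))


def fit_ml(table: AgePeriodTable, spec: BasisSpec | None = None,
           bump: CohortBump | None = None, *, tol_score: float = 1e-8,
           tol_deviance: float = 1e-10, max_iter: int = 100) -> FitResult:
    """Maximize the Poisson log-likelihood in (theta, beta_c) for a
    fixed bump (or without one).

    When ``spec`` is None, age and period are standardized to the
    table's cells.  The covariance is the inverse observed Fisher
    information (equal to the expected information under the log link).
    """
    if spec is None:
        spec = BasisSpec.from_table(table)
    est = PoissonBumpRegression(
        age_degree=spec.age_degree, period_degree=spec.period_degree,
        mu_c=None if bump is None else bump.mu_c,
        sigma_c=None if bump is None else bump.sigma_c,
        scaling=spec, tol_score=tol_score, tol_deviance=tol_deviance,
        max_iter=max_iter)
    X = np.column_stack([table.ages, table.periods])
    est.fit(X, table.deaths, exposure=table.person_years)
    return FitResult(theta=est.coef_, beta_c=est.bump_coef_,
                     covariance=est.covariance_, deviance_stat=est.deviance_,
                     converged=est.converged_, n_iter=est.n_iter_,
                     bump=bump, spec=spec)


def wald_tests(fit: FitResult) -> list[CoefficientTest]:
    """Per-coefficient Wald tests (beta_c last when present):
    z = estimate / SE against the standard normal, two-sided."""
    var = np.diag(fit.covariance)
    if np.any(var <= 0):
        bad = [fit.coef_names[j] for j in np.flatnonzero(var <= 0)]
        raise InferenceError(
            f"non-positive variance for coefficient(s) {bad}; the Fisher "
            "information is numerically singular")
    se = np.sqrt(var)
    out = []
    for name, est, s in zip(fit.coef_names, fit.coef, se):
        zval = est / s
        out.append(CoefficientTest(
            name=name, estimate=float(est), std_error=float(s),
            z_value=float(zval), p_value=float(2.0 * norm.sf(abs(zval)))))
    return out


def likelihood_ratio_test(fit_bump: FitResult,
                          fit_null: FitResult) -> tuple[float, float]:
    """Secondary report: LR statistic and p-value (chi-square, 1 df)
    for the bump coefficient, from nested fits on the same data."""
    stat = fit_null.deviance_stat - fit_bump.deviance_stat
    return float(stat), float(chi2.sf(max(stat, 0.0), df=1))
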