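"""Design bases for the varying-coefficient mortality model.

The log mortality rate over the age-period (Lexis) plane is modelled as

    beta0(a, p) = theta' x(a, p) + beta_c * phi(p - a; mu_c, sigma_c)

where ``x(a, p)`` is a tensor-product polynomial basis in (scaled) age and
period, and ``phi`` is a Gaussian density in birth year ``c = p - a``.  The
polynomial block absorbs smooth age, period and *global* cohort trends;
the Gaussian column captures a *local* excursion confined to cohorts born
within a few years of ``mu_c``.

The polynomial basis is evaluated on affinely rescaled age and period
(by default standardized to the observed cells) for numerical
conditioning; the Gaussian cohort basis is always evaluated on the raw
birth-year axis so that ``mu_c`` and ``sigma_c`` keep calendar-year units.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import norm

__all__ = ["BasisSpec", "CohortBump", "polynomial_row", "cohort_density",
           "design_matrix"]


@dataclass(frozen=True)
class BasisSpec:
    """Degrees and variable scaling of the polynomial age-period basis.

    The basis has ``(age_degree + 1) * (period_degree + 1)`` columns,
    ordered with the age powers cycling fastest::

        1, a, a^2, a^3, p, a*p, a^2*p, a^3*p, p^2, ..., a^3*p^3

    (shown for the default cubic-by-cubic case, 16 columns).  Age and
    period enter as ``(a - age_center) / age_scale`` and
    ``(p - period_center) / period_scale``.
    """

    age_degree: int = 3
    period_degree: int = 3
    age_center: float = 0.0
    age_scale: float = 1.0
    period_center: float = 0.0
    period_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.age_degree < 0 or self.period_degree < 0:
            raise ValueError("polynomial degrees must be >= 0")
        consts = (self.age_center, self.age_scale,
                  self.period_center, self.period_scale)
        if not all(np.isfinite(consts)):
            raise ValueError("scaling constants must be finite")
        if self.age_scale == 0 or self.period_scale == 0:
            raise ValueError("scale factors must be nonzero")

    @property
    def n_terms(self) -> int:
        return (self.age_degree + 1) * (self.period_degree + 1)

    @property
    def term_names(self) -> list[str]:
        def pow_name(sym: str, k: int) -> str:
            return "" if k == 0 else (sym if k == 1 else f"{sym}^{k}")

        names = []
        for j in range(self.period_degree + 1):
            for i in range(self.age_degree + 1):
                name = (pow_name("a", i) + pow_name("p", j)) or "1"
                names.append(name)
        return names

    @classmethod
    def from_cells(cls, ages, periods, age_degree: int = 3,
                   period_degree: int = 3) -> "BasisSpec":
        """Standardize age and period to mean 0, sd 1 over the given cells.

        Degenerate axes (a single distinct value) keep scale 1.
        """
        ages = np.asarray(ages, dtype=float)
        periods = np.asarray(periods, dtype=float)
        a_sd = float(np.std(ages)) or 1.0
        p_sd = float(np.std(periods)) or 1.0
        return cls(age_degree=age_degree, period_degree=period_degree,
                   age_center=float(np.mean(ages)), age_scale=a_sd,
                   period_center=float(np.mean(periods)), period_scale=p_sd)

    @classmethod
    def from_table(cls, table, age_degree: int = 3,
                   period_degree: int = 3) -> "BasisSpec":
        return cls.from_cells(table.ages, table.periods,
                              age_degree=age_degree,
                              period_degree=period_degree)

    def scale(self, a, p) -> tuple[np.ndarray, np.ndarray]:
        a = np.asarray(a, dtype=float)
        p = np.asarray(p, dtype=float)
        return ((a - self.age_center) / self.age_scale,
                (p - self.period_center) / self.period_scale)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSpec":
        return cls(**d)


@dataclass(frozen=True)
class CohortBump:
    """Center (``mu_c``, a birth year) and width (``sigma_c``, in years)
    of the Gaussian cohort basis."""

    mu_c: float
    sigma_c: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu_c) and np.isfinite(self.sigma_c)):
            raise ValueError("bump parameters must be finite")
        if self.sigma_c <= 0:
            raise ValueError("sigma_c must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortBump":
        return cls(**d)


def _poly_block(a, p, spec: BasisSpec) -> np.ndarray:
    """Tensor-product polynomial design block, shape (n, spec.n_terms)."""
    at, pt = spec.scale(a, p)
    at = np.atleast_1d(at)
    pt = np.atleast_1d(pt)
    a_pow = np.vander(at, spec.age_degree + 1, increasing=True)
    p_pow = np.vander(pt, spec.period_degree + 1, increasing=True)
    # column order: age powers fastest within each period power
    return (p_pow[:, :, None] * a_pow[:, None, :]).reshape(len(at), -1)


def polynomial_row(a: float, p: float, spec: BasisSpec) -> np.ndarray:
    """Evaluate the polynomial basis vector x(a, p) at a single cell."""
    if not (np.isfinite(a) and np.isfinite(p)):
        raise ValueError(f"non-finite age/period: a={a!r}, p={p!r}")
    return _poly_block(a, p, spec)[0]


def cohort_density(a, p, bump: CohortBump) -> np.ndarray | float:
    """Gaussian cohort basis: normal density with mean ``mu_c`` and sd
    ``sigma_c`` evaluated at the birth year ``p - a``.

    Peaks at ``1 / (sigma_c * sqrt(2*pi))`` on the diagonal
    ``p - a = mu_c``.
    """
    a = np.asarray(a, dtype=float)
    p = np.asarray(p, dtype=float)
    out = norm.pdf(p - a, loc=bump.mu_c, scale=bump.sigma_c)
    return float(out) if out.ndim == 0 else out


def design_matrix(table, spec: BasisSpec,
                  bump: CohortBump | None = None) -> np.ndarray:
    """Design matrix for an age-period table.

    Row j is ``x(a_j, p_j)``; when a bump is given its density column is
    appended last, so the coefficient vector is ``(theta..., beta_c)``.
    """
    if len(table) == 0:
        raise ValueError("empty table")
    return _design(table.ages, table.periods, spec, bump)


def _design(ages, periods, spec: BasisSpec,
            bump: CohortBump | None) -> np.ndarray:
    X = _poly_block(ages, periods, spec)
    if bump is not None:
        phi = np.atleast_1d(cohort_density(ages, periods, bump))
        X = np.column_stack([X, phi])
    return X
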