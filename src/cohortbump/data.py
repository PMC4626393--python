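"""Age-period table data model and I/O.

The observed data are cells of an age-period contingency table: deaths
``d`` and person-years of exposure ``z`` for each (age group, calendar
period) combination.  Grouped categories such as "40-44" are represented
by a single representative year per cell (the midpoint by default),
because the Gaussian cohort basis is evaluated at the real-valued birth
year ``p - a``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AgePeriodTable", "FormatError", "ValidationError",
           "read_table", "write_table", "read_wide_matrix"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("age", "period", "deaths", "person_years")

_RANGE_RE = re.compile(r"^\s*(-?\d+(?:\.\d+)?)\s*[-–—]\s*(-?\d+(?:\.\d+)?)\s*$")


class FormatError(ValueError):
    """A file does not have the expected layout (e.g. a missing column)."""


class ValidationError(ValueError):
    """Cell values violate the data model (negative deaths, bad exposure)."""


@dataclass
class AgePeriodTable:
    """Validated age-period mortality table.

    Parameters
    ----------
    cells : pandas.DataFrame
        Long-format table with columns ``age``, ``period`` (category
        midpoints in years), ``deaths`` (non-negative integer) and
        ``person_years`` (positive exposure).  (age, period) pairs must
        be unique; the birth year of a cell is ``period - age``.
    age_width, period_width : float
        Width in years of the age and period categories (informational;
        5-year groups are typical for registry tables).
    """

    cells: pd.DataFrame
    age_width: float = 5.0
    period_width: float = 5.0

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.cells).copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {missing}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].reset_index(drop=True)
        df["age"] = df["age"].astype(float)
        df["period"] = df["period"].astype(float)
        df["person_years"] = df["person_years"].astype(float)

        deaths = np.asarray(df["deaths"], dtype=float)
        bad = ~np.isfinite(deaths) | (deaths < 0) | (deaths != np.round(deaths))
        if bad.any():
            j = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                "deaths must be non-negative integers; offending cell "
                f"(age={df['age'][j]}, period={df['period'][j]}, "
                f"deaths={df['deaths'][j]!r})")
        df["deaths"] = deaths.astype(np.int64)

        z = df["person_years"].to_numpy()
        neg = ~np.isfinite(z) | (z < 0)
        if neg.any():
            j = int(np.flatnonzero(neg)[0])
            raise ValidationError(
                "person_years must be non-negative and finite; offending "
                f"cell (age={df['age'][j]}, period={df['period'][j]}, "
                f"person_years={df['person_years'][j]!r})")
        n_zero = int((z == 0).sum())
        if n_zero:
            # zero-exposure strata carry no Poisson information; drop them
            logger.info("dropping %d zero-exposure cell(s)", n_zero)
            df = df.loc[z > 0].reset_index(drop=True)

        if df.duplicated(subset=["age", "period"]).any():
            dup = df.loc[df.duplicated(subset=["age", "period"]),
                         ["age", "period"]].iloc[0]
            raise ValidationError(
                f"duplicate (age, period) cell: ({dup['age']}, {dup['period']})")
        self.cells = df

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def ages(self) -> np.ndarray:
        return self.cells["age"].to_numpy()

    @property
    def periods(self) -> np.ndarray:
        return self.cells["period"].to_numpy()

    @property
    def deaths(self) -> np.ndarray:
        return self.cells["deaths"].to_numpy()

    @property
    def person_years(self) -> np.ndarray:
        return self.cells["person_years"].to_numpy()

    def birth_years(self) -> np.ndarray:
        """Sorted distinct birth years ``period - age`` of the cells."""
        if len(self) == 0:
            raise ValidationError("empty table has no birth years")
        return np.unique(self.periods - self.ages)

    @property
    def birth_span(self) -> float:
        """Span (max - min) of observed birth years, in years."""
        c = self.birth_years()
        return float(c[-1] - c[0])


def _parse_category(value, convention: str) -> float:
    """Convert a category label to a representative year.

    Numeric values pass through.  A range label like ``"40-44"`` maps to
    its midpoint: 42.5 under the ``"right-open"`` convention (the group
    covers [40, 45)) or 42.0 under ``"closed"`` ([40, 44]).
    """
    try:
        return float(value)
    except (TypeError, ValueError):
        pass
    m = _RANGE_RE.match(str(value))
    if m is None:
        raise FormatError(f"cannot parse category label {value!r}")
    lo, hi = float(m.group(1)), float(m.group(2))
    if convention == "right-open":
        return (lo + hi + 1.0) / 2.0
    if convention == "closed":
        return (lo + hi) / 2.0
    raise ValueError(f"unknown label convention {convention!r}")


def read_table(path, dialect: dict | None = None, *,
               convention: str = "right-open",
               age_width: float = 5.0, period_width: float = 5.0,
               sep: str | None = None) -> AgePeriodTable:
    """Read a long-format delimited table into an :class:`AgePeriodTable`.

    Parameters
    ----------
    path : str or path-like
        CSV/TSV file with a header row.
    dialect : dict, optional
        Mapping from canonical names (``age``, ``period``, ``deaths``,
        ``person_years``) to the column names used in the file.
    convention : {"right-open", "closed"}
        How range labels like "40-44" are converted to midpoints
        (42.5 vs 42.0).
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    dialect = dialect or {}
    out = {}
    for canon in REQUIRED_COLUMNS:
        col = dialect.get(canon, canon)
        if col not in df.columns:
            raise FormatError(
                f"column {col!r} (for {canon!r}) not found in {path}")
        out[canon] = df[col]
    cells = pd.DataFrame(out)
    for col in ("age", "period"):
        if not pd.api.types.is_numeric_dtype(cells[col]):
            cells[col] = [_parse_category(v, convention) for v in cells[col]]
    return AgePeriodTable(cells, age_width=age_width,
                          period_width=period_width)


def write_table(table: AgePeriodTable, path) -> None:
    """Write a table as canonical long-format CSV (round-trips with
    :func:`read_table`)."""
    table.cells.to_csv(path, index=False)


def read_wide_matrix(path, value_name: str = "rate") -> pd.DataFrame:
    """Read a wide age-by-period matrix (rows = age groups, columns =
    periods) and melt it to long form.

    This is a display-path convenience for rate matrices; it carries no
    exposure information, so the result is a plain DataFrame with
    columns ``age``, ``period`` and ``value_name``, not an
    :class:`AgePeriodTable`.
    """
    df = pd.read_csv(path, index_col=0)
    long = df.reset_index(names="age").melt(
        id_vars="age", var_name="period", value_name=value_name)
    long["age"] = [_parse_category(v, "right-open") for v in long["age"]]
    long["period"] = [_parse_category(v, "right-open") for v in long["period"]]
    return long.sort_values(["age", "period"], ignore_index=True)
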