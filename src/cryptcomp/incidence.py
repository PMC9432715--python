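"""Age-specific incidence tables: reading, validation and preprocessing.

Registry extracts (SEER-style) report diagnoses in eighteen 5-year age
groups with an open-ended 85+ group.  Preparation for model fitting follows
the registry conventions: rates are assigned to the group midpoints, the
85+ group is dropped (person-years decline too rapidly beyond 85), 95%
confidence intervals come from a Poisson model of the counts expected under
the US Standard population 2000, and rates above a screening-age threshold
may be inflated by a multiplicative factor (default 4/3 above 55 years) to
compensate for incidence removed by colonoscopy screening and resection.

CSV schema (comma-separated, UTF-8, header required)::

    cancer_site,age_lo,age_hi,count,person_years,rate_per_100k

``age_hi`` empty encodes the open-ended group.  ``rate_per_100k`` may be
omitted when ``count`` and ``person_years`` are present, and vice versa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgeGroupRecord",
    "IncidenceTable",
    "StandardPopulation",
    "SchemaError",
    "StateError",
    "us_standard_2000",
    "load_incidence_csv",
    "write_incidence_csv",
    "poisson_intervals",
    "adjust_for_screening",
    "prepare_for_fit",
]

log = logging.getLogger(__name__)

PER_100K = 1e5


class SchemaError(ValueError):
    """An incidence table violates the CSV schema or its invariants."""


class StateError(RuntimeError):
    """A preprocessing step was applied in an invalid order."""


@dataclass(frozen=True)
class AgeGroupRecord:
    """One 5-year age group (or the open 85+ group) of an incidence table."""

    age_lo: float
    age_hi: float | None  # None encodes the open-ended group
    rate: float  # per 100,000 person-years
    count: float | None = None
    person_years: float | None = None
    ci_lo: float | None = None
    ci_hi: float | None = None
    sigma: float | None = None  # rate-scale SD from the 95% CI half-width

    @property
    def is_open(self) -> bool:
        return self.age_hi is None

    @property
    def midpoint(self) -> float:
        """Midpoint age of a closed group; open groups have no midpoint."""
        if self.is_open:
            raise ValueError("open-ended age group has no midpoint")
        return 0.5 * (self.age_lo + self.age_hi)


@dataclass(frozen=True)
class IncidenceTable:
    """Ordered, contiguous collection of age-group records."""

    records: tuple[AgeGroupRecord, ...]
    cancer_site: str = "colon"
    adjusted: bool = False
    adjustment_factor: float | None = None
    adjustment_min_age: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        prev_hi = 0.0
        for k, r in enumerate(self.records):
            if r.age_lo != prev_hi:
                raise SchemaError(
                    f"age groups must be contiguous from 0: row {k} starts at "
                    f"{r.age_lo}, expected {prev_hi}"
                )
            if not r.is_open:
                if r.age_hi - r.age_lo != 5:
                    raise SchemaError(
                        f"row {k}: closed groups must span 5 years "
                        f"({r.age_lo}-{r.age_hi})"
                    )
                prev_hi = r.age_hi
            elif k != len(self.records) - 1:
                raise SchemaError(f"row {k}: open-ended group must come last")
            if r.rate < 0 or (r.count is not None and r.count < 0):
                raise SchemaError(f"row {k}: negative rate or count")
            if r.person_years is not None and r.person_years <= 0:
                raise SchemaError(f"row {k}: person_years must be positive")
            if r.ci_lo is not None and r.ci_hi is not None:
                if not r.ci_lo <= r.rate <= r.ci_hi:
                    raise SchemaError(f"row {k}: rate outside its CI")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([r.midpoint for r in self.records if not r.is_open])

    @property
    def rates(self) -> np.ndarray:
        return np.array([r.rate for r in self.records])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array(
            [r.sigma if r.sigma is not None else np.nan for r in self.records]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cancer_site": self.cancer_site,
                "age_lo": [r.age_lo for r in self.records],
                "age_hi": [r.age_hi for r in self.records],
                "count": [r.count for r in self.records],
                "person_years": [r.person_years for r in self.records],
                "rate_per_100k": [r.rate for r in self.records],
            }
        )


@dataclass(frozen=True)
class StandardPopulation:
    """Per-age-group person counts of a standard population."""

    age_lo: np.ndarray
    population: np.ndarray
    name: str = "US Standard 2000"

    def __post_init__(self) -> None:
        if np.any(self.population <= 0):
            raise ValueError("standard-population counts must be positive")

    def count_for(self, age_lo: float) -> float:
        idx = np.nonzero(self.age_lo == age_lo)[0]
        if idx.size != 1:
            raise ValueError(f"no standard-population group starting at {age_lo}")
        return float(self.population[idx[0]])


@lru_cache(maxsize=1)
def us_standard_2000() -> StandardPopulation:
    """US Standard population 2000 in the 18-group scheme (85+ collapsed)."""
    ref = resources.files("cryptcomp.data").joinpath("us_standard_2000.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return StandardPopulation(
        age_lo=df["age_lo"].to_numpy(dtype=float),
        population=df["population"].to_numpy(dtype=float),
    )


_REQUIRED_COLS = {"cancer_site", "age_lo", "age_hi"}


def load_incidence_csv(path) -> IncidenceTable:
    """Read an incidence table from the documented CSV schema.

    The rate is recomputed as ``count / person_years * 1e5`` whenever the
    ``rate_per_100k`` column is absent or empty for a row; a row providing
    neither a rate nor (count, person_years) is a schema error.
    """
    df = pd.read_csv(path)
    missing = _REQUIRED_COLS - set(df.columns)
    if missing:
        raise SchemaError(f"missing required columns: {sorted(missing)}")
    records = []
    for k, row in df.iterrows():
        count = None if "count" not in df or pd.isna(row.get("count")) else float(row["count"])
        py = (
            None
            if "person_years" not in df or pd.isna(row.get("person_years"))
            else float(row["person_years"])
        )
        rate = (
            None
            if "rate_per_100k" not in df or pd.isna(row.get("rate_per_100k"))
            else float(row["rate_per_100k"])
        )
        if rate is None:
            if count is None or py is None:
                raise SchemaError(
                    f"row {k}: need rate_per_100k or both count and person_years"
                )
            rate = count / py * PER_100K
        age_hi = None if pd.isna(row["age_hi"]) else float(row["age_hi"])
        records.append(
            AgeGroupRecord(
                age_lo=float(row["age_lo"]),
                age_hi=age_hi,
                rate=rate,
                count=count,
                person_years=py,
            )
        )
    site = str(df["cancer_site"].iloc[0]) if len(df) else "unknown"
    return IncidenceTable(records=tuple(records), cancer_site=site)


def write_incidence_csv(table: IncidenceTable, path) -> None:
    """Write a table back to the CSV schema (inverse of the loader)."""
    table.to_frame().to_csv(path, index=False)


def _poisson_ci_counts(mu: float) -> tuple[float, float]:
    """[2.5%, 97.5%] quantiles of Poisson(mu) on the count scale."""
    if mu <= 0:
        return 0.0, 0.0
    return float(stats.poisson.ppf(0.025, mu)), float(stats.poisson.ppf(0.975, mu))


def poisson_intervals(
    table: IncidenceTable, std_pop: StandardPopulation | None = None
) -> IncidenceTable:
    """Attach Poisson 95% confidence intervals and rate-scale sigmas.

    For each group the expected count under the standard population is
    ``mu = rate * pop / 1e5``; the interval is the [2.5%, 97.5%] Poisson
    quantile range of that count, rescaled back to rates, and
    ``sigma = (ci_hi - ci_lo) / (2 * 1.96)`` is stored for chi-squared
    weighting.  Zero-mean groups get a one-sided sigma from the exact 97.5%
    Poisson upper bound so that weights stay finite.
    """
    if std_pop is None:
        std_pop = us_standard_2000()
    new_records = []
    for r in table.records:
        pop = std_pop.count_for(r.age_lo)
        mu = r.rate * pop / PER_100K
        lo, hi = _poisson_ci_counts(mu)
        ci_lo = lo * PER_100K / pop
        ci_hi = hi * PER_100K / pop
        if mu > 0:
            sigma = (ci_hi - ci_lo) / (2.0 * 1.96)
        else:
            # exact one-sided bound: P(X = 0 | mu) = 0.025 at mu = -ln(0.025)
            sigma = (-np.log(0.025)) * PER_100K / pop / 1.96
        new_records.append(replace(r, ci_lo=ci_lo, ci_hi=ci_hi, sigma=sigma))
    log.info(
        "poisson_intervals: %d groups against %s", len(new_records), std_pop.name
    )
    return replace(table, records=tuple(new_records))


def adjust_for_screening(
    table: IncidenceTable, factor: float = 4.0 / 3.0, min_age: float = 55.0
) -> IncidenceTable:
    """Inflate rates of groups with ``age_lo >= min_age`` by ``factor``.

    Compensates for incidence removed by endoscopic screening and resection
    at older ages; counts are scaled alongside rates so the table stays
    internally consistent.  Applying the adjustment twice is an error.
    """
    if table.adjusted:
        raise StateError("table is already screening-adjusted")
    new_records = []
    for r in table.records:
        if r.age_lo >= min_age:
            r = replace(
                r,
                rate=r.rate * factor,
                count=None if r.count is None else r.count * factor,
                ci_lo=None if r.ci_lo is None else r.ci_lo * factor,
                ci_hi=None if r.ci_hi is None else r.ci_hi * factor,
                sigma=None if r.sigma is None else r.sigma * factor,
            )
        new_records.append(r)
    log.info(
        "adjust_for_screening: factor %.4g applied to groups with age_lo >= %g",
        factor,
        min_age,
    )
    return replace(
        table,
        records=tuple(new_records),
        adjusted=True,
        adjustment_factor=factor,
        adjustment_min_age=min_age,
    )


def prepare_for_fit(
    table: IncidenceTable, std_pop: StandardPopulation | None = None
) -> IncidenceTable:
    """Drop the open 85+ group and ensure intervals are present.

    The returned table contains only closed 5-year groups with midpoints;
    Poisson intervals are computed if any record lacks them.  Idempotent on
    already-prepared tables.
    """
    records = tuple(r for r in table.records if not r.is_open)
    usable = [r for r in records if r.rate is not None]
    if len(usable) < 5:
        raise SchemaError(
            f"insufficient data: only {len(usable)} usable closed groups (need >= 5)"
        )
    out = replace(table, records=records)
    if any(r.sigma is None for r in records):
        out = poisson_intervals(out, std_pop)
    log.info(
        "prepare_for_fit: %d closed groups, midpoints %.1f-%.1f",
        len(out),
        out.midpoints.min(),
        out.midpoints.max(),
    )
    return out
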