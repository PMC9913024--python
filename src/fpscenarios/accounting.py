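"""Demographic accounting: proportions to absolute numbers, and aggregation.

Scenario proportions are turned into counts of women by multiplying by the
number of women of reproductive age (WRA, 15-49) in the country and target
year, in thousands. Country results are summed over countries; the aggregate
percent of demand satisfied is the ratio of the summed counts
(sum users / (sum users + sum unmet)), never the mean of country
percentages. Full precision is kept internally and in CSV output; rounding
to a fixed number of significant figures happens only when the comparison is
rendered, and the difference column is computed before any rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, InvariantError, ParseError
from .trajectories import CountryScenarioProportions

#: Exact header of the country-level results CSV.
RESULT_COLUMNS = (
    "country",
    "scenario",
    "demand_satisfied",
    "users_modern_thousands",
    "unmet_modern_thousands",
    "unintended_pregnancies_thousands",
    "total_cost_usd_thousands",
)

#: Row labels of the scenario comparison, in report order.
QUANTITY_ROWS = (
    "% of demand satisfied by modern methods",
    "No. of women using modern methods (000s)",
    "No. of women with an unmet need for modern methods (000s)",
    "No. of unintended pregnancies (000s)",
    "Annual total direct costs ($) (000s)",
)


@dataclass(frozen=True)
class PopulationTable:
    """WRA counts in thousands, keyed by (country, year); strictly positive."""

    counts: pd.Series

    def __post_init__(self) -> None:
        counts = self.counts.astype(float)
        if counts.index.nlevels != 2:
            raise InputError("population table must be keyed by (country, year)")
        counts.index = counts.index.set_levels(
            [counts.index.levels[0].astype(str), counts.index.levels[1].astype(int)]
        )
        if not np.all(np.isfinite(counts.to_numpy())) or np.any(counts.to_numpy() <= 0):
            raise InputError("WRA counts must be finite and strictly positive")
        object.__setattr__(self, "counts", counts)

    @property
    def countries(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.counts.index.get_level_values(0)))

    def wra(self, country: str, year: int) -> float:
        try:
            return float(self.counts.loc[(str(country), int(year))])
        except KeyError:
            raise InputError(f"no WRA count for country {country!r}, year {year}") from None

    def to_frame(self) -> pd.DataFrame:
        return (
            self.counts.rename("wra_thousands")
            .rename_axis(["country", "year"])
            .reset_index()
        )


def read_population(path: str | Path) -> PopulationTable:
    """Read ``country,year,wra_thousands`` CSV."""
    df = pd.read_csv(path)
    missing = [c for c in ("country", "year", "wra_thousands") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s): {', '.join(missing)}")
    return PopulationTable(counts=df.set_index(["country", "year"])["wra_thousands"])


def write_population(pop: PopulationTable, path: str | Path) -> None:
    pop.to_frame().to_csv(path, index=False)


def absolute_numbers(
    props: CountryScenarioProportions, pop: PopulationTable
) -> tuple[float, float]:
    """(modern users, women with unmet need for modern methods), thousands:
    the scenario proportions times the target-year WRA count."""
    wra = pop.wra(props.country, props.target_year)
    return props.modern * wra, props.trad_plus_unmet * wra


@dataclass(frozen=True)
class CountryScenarioResult:
    """One country's scenario outputs. Counts are thousands of women (or
    pregnancies) per year; cost is USD thousands per year."""

    country: str
    scenario: str
    demand_satisfied: float
    users_modern: float
    unmet_modern: float
    unintended_pregnancies: float
    total_cost: float

    def __post_init__(self) -> None:
        total = self.users_modern + self.unmet_modern
        if total > 0:
            implied = self.users_modern / total
            if not math.isclose(implied, self.demand_satisfied, rel_tol=1e-9, abs_tol=1e-12):
                raise InvariantError(
                    f"country {self.country}: demand satisfied {self.demand_satisfied!r} "
                    f"inconsistent with users/(users+unmet) = {implied!r}"
                )


@dataclass(frozen=True)
class AggregateRow:
    """Country sums for one scenario, plus the set of countries summed."""

    scenario: str
    countries: tuple[str, ...]
    users_modern: float
    unmet_modern: float
    unintended_pregnancies: float
    total_cost: float

    @property
    def percent_demand_satisfied(self) -> float:
        total = self.users_modern + self.unmet_modern
        return 100.0 * self.users_modern / total if total > 0 else 0.0


def aggregate(results: Sequence[CountryScenarioResult]) -> AggregateRow:
    """Sum country results for a single scenario. The aggregate percent of
    demand satisfied is the ratio of sums."""
    if not results:
        raise InputError("cannot aggregate an empty result list")
    scenarios = {r.scenario for r in results}
    if len(scenarios) != 1:
        raise InputError(f"aggregate expects one scenario, got {sorted(scenarios)}")
    countries = [r.country for r in results]
    dupes = sorted({c for c in countries if countries.count(c) > 1})
    if dupes:
        raise InputError(f"duplicate country in results: {', '.join(dupes)}")
    # fsum: exactly rounded, hence independent of country order.
    return AggregateRow(
        scenario=results[0].scenario,
        countries=tuple(sorted(countries)),
        users_modern=math.fsum(r.users_modern for r in results),
        unmet_modern=math.fsum(r.unmet_modern for r in results),
        unintended_pregnancies=math.fsum(r.unintended_pregnancies for r in results),
        total_cost=math.fsum(r.total_cost for r in results),
    )


def round_sigfigs(x: float, sigfigs: int = 3) -> float:
    """Round to ``sigfigs`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sigfigs - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass(frozen=True)
class ScenarioComparison:
    """Side-by-side scenario aggregates with a difference column (last
    scenario minus first), all at full precision."""

    rows: tuple[AggregateRow, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise InputError("comparison needs at least one scenario")
        object.__setattr__(self, "rows", tuple(self.rows))

    @property
    def has_difference(self) -> bool:
        return len(self.rows) >= 2

    def _values(self, row: AggregateRow) -> list[float]:
        return [
            row.percent_demand_satisfied,
            row.users_modern,
            row.unmet_modern,
            row.unintended_pregnancies,
            row.total_cost,
        ]

    def to_frame(self) -> pd.DataFrame:
        data = {row.scenario: self._values(row) for row in self.rows}
        df = pd.DataFrame(data, index=list(QUANTITY_ROWS))
        if self.has_difference:
            df["difference"] = df[self.rows[-1].scenario] - df[self.rows[0].scenario]
        return df.rename_axis("quantity")

    def render(self, sigfigs: int = 3) -> str:
        """Aligned text table; counts and costs rounded to ``sigfigs``
        significant figures, the percent row to the nearest whole percent
        (differences are computed before rounding)."""
        df = self.to_frame()

        def fmt(label: str, x: float) -> str:
            if label == QUANTITY_ROWS[0]:
                return f"{round(x):.0f}%"
            r = round_sigfigs(x, sigfigs)
            return f"{r:,.0f}" if abs(r) >= 1 or r == 0 else f"{r:g}"

        out = df.copy()
        for col in out.columns:
            out[col] = [fmt(label, x) for label, x in zip(df.index, df[col])]
        return out.reset_index().to_string(index=False)


def compare(current: AggregateRow, accelerated: AggregateRow) -> ScenarioComparison:
    """Compare two scenario aggregates over the same country set; the
    difference column is accelerated minus current on unrounded values."""
    cur, acc = set(current.countries), set(accelerated.countries)
    if cur != acc:
        diff = sorted(cur.symmetric_difference(acc))
        raise InputError(f"scenario country sets differ: {', '.join(diff)}")
    return ScenarioComparison(rows=(current, accelerated))


# -- country-level results CSV ----------------------------------------------


def results_to_frame(results: Iterable[CountryScenarioResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "country": r.country,
                "scenario": r.scenario,
                "demand_satisfied": r.demand_satisfied,
                "users_modern_thousands": r.users_modern,
                "unmet_modern_thousands": r.unmet_modern,
                "unintended_pregnancies_thousands": r.unintended_pregnancies,
                "total_cost_usd_thousands": r.total_cost,
            }
            for r in results
        ],
        columns=list(RESULT_COLUMNS),
    )


def write_results(results: Iterable[CountryScenarioResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a country-level results CSV (the machine twin of the published
    country appendix table)."""
    df = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df
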