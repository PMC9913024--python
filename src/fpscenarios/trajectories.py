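"""Posterior trajectory samples and percentile-based scenario construction.

The probabilistic input to the whole pipeline is a set of posterior
trajectory samples: for each country and each draw from the joint projection
model, a time series over 2019-2030 of three proportions among women of
reproductive age (WRA, 15-49):

* ``modern`` -- using a modern contraceptive method,
* ``traditional`` -- using a traditional method,
* ``unmet`` -- with an unmet need for family planning (any method).

Demand satisfied with modern methods (SDG indicator 3.7.1) is
``modern / (modern + traditional + unmet)``; the denominator is total demand
for family planning. Women using a traditional method or with unmet need
together form the "unmet need for modern methods" group.

Scenarios are built from the country-specific distribution of the *change*
in demand satisfied between a baseline year and a target year, computed
within each trajectory so that uncertainty in the baseline level propagates.
The scenario level in the target year is the median baseline level plus a
chosen percentile of that change distribution (50th = current progress,
90th = accelerated progress), clipped to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InputError, ParseError

log = logging.getLogger(__name__)

#: Exact header of the long-format trajectory CSV.
TRAJECTORY_COLUMNS = ("country", "sample", "year", "modern", "traditional", "unmet")

# Slack for the componentwise simplex check on user-supplied proportions.
_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ScenarioSpec:
    """A named scenario: a percentile of the change distribution plus the
    baseline and target years it spans.

    percentile 50 reads "there is a 50% chance the realised change is at this
    level or higher"; percentile 90 reads "a one in ten chance".
    """

    name: str
    percentile: float
    baseline_year: int = 2019
    target_year: int = 2030

    def __post_init__(self) -> None:
        if not np.isfinite(self.percentile) or not 0.0 < self.percentile < 100.0:
            raise InputError(
                f"scenario {self.name!r}: percentile must lie in (0, 100), got {self.percentile}"
            )
        if self.baseline_year >= self.target_year:
            raise InputError(
                f"scenario {self.name!r}: baseline_year {self.baseline_year} must precede "
                f"target_year {self.target_year}"
            )


#: The two default scenarios: business-as-usual and accelerated progress.
CURRENT_PROGRESS = ScenarioSpec("current", 50.0)
ACCELERATED_PROGRESS = ScenarioSpec("accelerated", 90.0)


@dataclass(frozen=True, eq=False)
class TrajectorySet:
    """Posterior samples of (modern, traditional, unmet) proportions.

    ``values`` has shape (n_countries, n_samples, n_years, 3), last axis
    ordered (modern, traditional, unmet). Every entry lies in [0, 1] and each
    triple sums to at most 1; every (country, sample) pair covers every year.
    """

    countries: tuple[str, ...]
    years: tuple[int, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "countries", tuple(str(c) for c in self.countries))
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        if v.ndim != 4 or v.shape[3] != 3:
            raise InputError(
                f"trajectory values must have shape (countries, samples, years, 3), got {v.shape}"
            )
        if v.shape[0] != len(self.countries) or v.shape[2] != len(self.years):
            raise InputError("trajectory value dimensions do not match country/year labels")
        if v.shape[1] < 2:
            raise InputError(f"need at least 2 posterior samples, got {v.shape[1]}")
        if len(set(self.countries)) != len(self.countries):
            raise InputError("duplicate country identifiers")
        if list(self.years) != sorted(set(self.years)):
            raise InputError("years must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise InputError("trajectory values contain non-finite entries")
        if v.min() < -_SUM_TOL or v.max() > 1.0 + _SUM_TOL:
            raise InputError("trajectory proportions must lie in [0, 1]")
        sums = v.sum(axis=3)
        if sums.max() > 1.0 + _SUM_TOL:
            raise InputError(
                "modern + traditional + unmet exceeds 1 for some (country, sample, year)"
            )

    # -- indexing helpers ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def country_index(self, country: str) -> int:
        try:
            return self.countries.index(country)
        except ValueError:
            raise InputError(f"country {country!r} not present in trajectory set") from None

    def year_index(self, year: int) -> int:
        try:
            return self.years.index(int(year))
        except ValueError:
            raise InputError(f"year {year} not present in trajectory set") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrajectorySet):
            return NotImplemented
        return (
            self.countries == other.countries
            and self.years == other.years
            and np.array_equal(self.values, other.values)
        )

    # -- long-format conversion ---------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        c_n, s_n, y_n, _ = self.values.shape
        idx = pd.MultiIndex.from_product(
            [self.countries, range(s_n), self.years], names=["country", "sample", "year"]
        )
        df = pd.DataFrame(
            self.values.reshape(-1, 3), columns=["modern", "traditional", "unmet"], index=idx
        )
        return df.reset_index()

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrajectorySet":
        missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"missing required column(s): {', '.join(missing)}")
        df = df.loc[:, list(TRAJECTORY_COLUMNS)].copy()

        bad_lines: list[int] = []
        for col in ("sample", "year", "modern", "traditional", "unmet"):
            num = pd.to_numeric(df[col], errors="coerce")
            bad_lines.extend((df.index[num.isna()] + 2).tolist())
            df[col] = num
        prop = df[["modern", "traditional", "unmet"]]
        with np.errstate(invalid="ignore"):
            out_of_range = (
                (prop < -_SUM_TOL).any(axis=1)
                | (prop > 1 + _SUM_TOL).any(axis=1)
                | (prop.sum(axis=1) > 1 + _SUM_TOL)
            ) & prop.notna().all(axis=1)
        bad_lines.extend((df.index[out_of_range] + 2).tolist())
        if bad_lines:
            shown = ", ".join(str(n) for n in sorted(set(bad_lines))[:20])
            raise ParseError(
                f"malformed trajectory rows (non-numeric or off-simplex) at line(s): {shown}"
            )

        countries = tuple(sorted(df["country"].astype(str).unique()))
        samples = sorted(df["sample"].astype(int).unique())
        years = tuple(sorted(df["year"].astype(int).unique()))
        indexed = df.set_index(["country", "sample", "year"])
        if indexed.index.duplicated().any():
            dupes = indexed.index[indexed.index.duplicated()][:5].tolist()
            raise ParseError(f"duplicate (country, sample, year) rows, e.g. {dupes}")
        full = pd.MultiIndex.from_product([countries, samples, years])
        reindexed = indexed.reindex(full)
        if reindexed[["modern", "traditional", "unmet"]].isna().any().any():
            gaps = full[reindexed["modern"].isna()][:5].tolist()
            raise ParseError(f"gaps in the (country, sample, year) grid, e.g. {gaps}")
        values = reindexed[["modern", "traditional", "unmet"]].to_numpy().reshape(
            len(countries), len(samples), len(years), 3
        )
        return cls(countries=countries, years=years, values=values)


def write_trajectories(traj: TrajectorySet, path: str | Path) -> None:
    """Write a trajectory set as long-format CSV (lossless round-trip)."""
    # 17 significant digits round-trip any float64 exactly.
    traj.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_trajectories(path: str | Path) -> TrajectorySet:
    """Read a long-format trajectory CSV; schema violations raise
    :class:`~fpscenarios.errors.ParseError` naming columns or line numbers."""
    try:
        # round_trip parsing: recover the exact float64 the writer printed.
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"cannot parse trajectory CSV {path}: {exc}") from exc
    return TrajectorySet.from_frame(df)


# -- scenario machinery -----------------------------------------------------


def demand_satisfied(modern, traditional, unmet):
    """Proportion of demand for family planning satisfied with modern methods.

    ``modern / (modern + traditional + unmet)``; total demand is any-method
    use plus unmet need. Zero total demand is defined as 0 (with a warning)
    rather than an error so all-zero toy inputs flow through. Accepts scalars
    or broadcastable arrays.
    """
    m = np.asarray(modern, dtype=float)
    t = np.asarray(traditional, dtype=float)
    u = np.asarray(unmet, dtype=float)
    for name, x in (("modern", m), ("traditional", t), ("unmet", u)):
        if np.any(x < -_SUM_TOL) or np.any(x > 1 + _SUM_TOL):
            raise InputError(f"{name} proportion outside [0, 1]")
    total = m + t + u
    if np.any(total > 1 + _SUM_TOL):
        raise InputError("modern + traditional + unmet exceeds 1")
    zero = total <= 0
    if np.any(zero):
        log.warning("zero total demand encountered; demand satisfied defined as 0")
    ds = np.divide(m, total, out=np.zeros_like(m + total), where=~zero)
    if ds.ndim == 0:
        return float(ds)
    return ds


def quantile(values: Iterable[float] | np.ndarray, p: float) -> float:
    """Percentile ``p`` of ``values`` by linear interpolation between order
    statistics (the common "type 7" rule; p=0 gives the minimum, p=100 the
    maximum). p=50 on an odd-length list is the middle order statistic."""
    v = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    if v.size == 0:
        raise InputError("quantile of an empty list")
    if not np.all(np.isfinite(v)):
        raise InputError("quantile input contains non-finite values")
    if not np.isfinite(p) or not 0.0 <= p <= 100.0:
        raise InputError(f"percentile must lie in [0, 100], got {p}")
    return float(np.quantile(v, p / 100.0, method="linear"))


def change_distribution(traj: TrajectorySet, country: str, spec: ScenarioSpec) -> np.ndarray:
    """Per-trajectory change in demand satisfied between the baseline and
    target years: element ``s`` is DS(target) - DS(baseline) computed within
    trajectory ``s``, so the distribution carries baseline uncertainty and is
    independent of the central start and end levels."""
    ci = traj.country_index(country)
    bi = traj.year_index(spec.baseline_year)
    ti = traj.year_index(spec.target_year)
    base = traj.values[ci, :, bi, :]
    targ = traj.values[ci, :, ti, :]
    ds_base = demand_satisfied(base[:, 0], base[:, 1], base[:, 2])
    ds_targ = demand_satisfied(targ[:, 0], targ[:, 1], targ[:, 2])
    return np.asarray(ds_targ - ds_base, dtype=float)


@dataclass(frozen=True)
class CountryScenarioProportions:
    """One country's scenario proportions in the target year.

    ``trad_plus_unmet`` is the unmet need for *modern* methods as a
    proportion of WRA (traditional users plus women with unmet need).
    The accounting identity ``modern + trad_plus_unmet == total_demand`` and
    ``demand_satisfied == modern / total_demand`` hold by construction.
    """

    country: str
    target_year: int
    demand_satisfied: float
    modern: float
    trad_plus_unmet: float
    total_demand: float
    clipped: bool = False


def scenario_proportions(
    traj: TrajectorySet, country: str, spec: ScenarioSpec
) -> CountryScenarioProportions:
    """Build a country's scenario for the target year.

    Demand satisfied = clip(median baseline DS + percentile of the change
    distribution, 0, 1). The target-year total demand is the median over
    samples; it is split into modern use and unmet-for-modern by the scenario
    DS, which preserves the identity DS = users / (users + unmet) exactly.
    """
    ci = traj.country_index(country)
    bi = traj.year_index(spec.baseline_year)
    ti = traj.year_index(spec.target_year)

    base = traj.values[ci, :, bi, :]
    ds_base = demand_satisfied(base[:, 0], base[:, 1], base[:, 2])
    baseline_median = quantile(ds_base, 50.0)

    changes = change_distribution(traj, country, spec)
    change_q = quantile(changes, spec.percentile)

    ds_target = baseline_median + change_q
    clipped = not 0.0 <= ds_target <= 1.0
    if clipped:
        log.warning(
            "country %s scenario %s: demand satisfied %.4f clipped to [0, 1]",
            country,
            spec.name,
            ds_target,
        )
        ds_target = float(np.clip(ds_target, 0.0, 1.0))

    targ = traj.values[ci, :, ti, :]
    total_demand = quantile(targ.sum(axis=1), 50.0)
    modern = ds_target * total_demand
    trad_plus_unmet = total_demand - modern
    log.debug(
        "country=%s scenario=%s baseline_median_ds=%.4f change_q=%.4f ds=%.4f clipped=%s",
        country,
        spec.name,
        baseline_median,
        change_q,
        ds_target,
        clipped,
    )
    return CountryScenarioProportions(
        country=country,
        target_year=spec.target_year,
        demand_satisfied=ds_target,
        modern=modern,
        trad_plus_unmet=trad_plus_unmet,
        total_demand=total_demand,
        clipped=clipped,
    )
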