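"""Direct cost projection for contraceptive services.

Per-user annual costs are the sum of three base-year (2020) components --
personnel, drugs & supplies, and the commodity itself -- each carried to the
target year under its own inflation rule:

* personnel: country-specific GDP-deflator rates for 2021-2024, then the
  arithmetic mean of those four rates for every year 2025 onwards;
* drugs & supplies: a single constant US inflation rate (the 2015-2019
  average) compounded from 2020;
* commodity: not inflated over 2020-2030 (observed commodity prices for the
  relevant supplies fell over 2015-2019, so holding them flat is
  conservative).

All compounding is multiplicative and annual from the 2020 base; costs are
nominal target-year USD with no discounting. Scenario totals are the
mix-weighted per-user cost times the number of modern users.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ParseError
from .impact import MethodMix

#: Costs are expressed in USD of this base year; all factors equal 1 here.
BASE_YEAR = 2020
#: Years with explicit country GDP-deflator rates.
DEFLATOR_YEARS = (2021, 2022, 2023, 2024)
_MAX_YEAR = 2030

_COST_COLUMNS = ("method", "personnel", "drugs_supplies", "commodity")


def _check_year(target_year: int) -> int:
    target_year = int(target_year)
    if not BASE_YEAR <= target_year <= _MAX_YEAR:
        raise InputError(
            f"target year must lie in [{BASE_YEAR}, {_MAX_YEAR}], got {target_year}"
        )
    return target_year


def personnel_factor(rates_2021_2024: Sequence[float], target_year: int) -> float:
    """Cumulative personnel inflation multiplier from 2020 to ``target_year``:
    the product of (1 + rate) over 2021..min(target_year, 2024), times
    (1 + mean rate) for each year beyond 2024."""
    target_year = _check_year(target_year)
    rates = np.asarray(rates_2021_2024, dtype=float)
    if rates.shape != (4,) or not np.all(np.isfinite(rates)):
        raise InputError("personnel inflation needs four finite annual rates (2021-2024)")
    factor = 1.0
    for year, rate in zip(DEFLATOR_YEARS, rates):
        if year <= target_year:
            factor *= 1.0 + rate
    extra_years = max(0, target_year - DEFLATOR_YEARS[-1])
    factor *= (1.0 + rates.mean()) ** extra_years
    return factor


def drugs_supplies_factor(us_rate: float, target_year: int) -> float:
    """Drugs & supplies multiplier: (1 + us_rate) ** (target_year - 2020)."""
    target_year = _check_year(target_year)
    if not np.isfinite(us_rate) or us_rate < 0:
        raise InputError(f"US inflation rate must be finite and >= 0, got {us_rate}")
    return (1.0 + us_rate) ** (target_year - BASE_YEAR)


def commodity_factor(target_year: int) -> float:
    """Commodity costs are not inflated: always 1 within 2020-2030."""
    _check_year(target_year)
    return 1.0


@dataclass(frozen=True)
class InflationInputs:
    """Country GDP-deflator rates for 2021-2024 plus the constant US rate."""

    rates: pd.DataFrame  # index: country; columns rate_2021..rate_2024
    us_rate: float

    def __post_init__(self) -> None:
        expected = [f"rate_{y}" for y in DEFLATOR_YEARS]
        missing = [c for c in expected if c not in self.rates.columns]
        if missing:
            raise ParseError(f"inflation table missing column(s): {', '.join(missing)}")
        frame = self.rates[expected].astype(float)
        frame.index = frame.index.astype(str)
        object.__setattr__(self, "rates", frame)
        if not np.all(np.isfinite(frame.to_numpy())):
            raise InputError("inflation rates must be finite")
        if not np.isfinite(self.us_rate) or self.us_rate < 0:
            raise InputError(f"us_rate must be finite and >= 0, got {self.us_rate}")

    @property
    def countries(self) -> tuple[str, ...]:
        return tuple(self.rates.index)

    def country_rates(self, country: str) -> np.ndarray:
        try:
            return self.rates.loc[str(country)].to_numpy(dtype=float)
        except KeyError:
            raise InputError(f"no inflation rates for country {country!r}") from None


def read_inflation(path: str | Path, us_rate: float) -> InflationInputs:
    """Read ``country,rate_2021,rate_2022,rate_2023,rate_2024`` CSV; the US
    rate comes from the run configuration, not the file."""
    df = pd.read_csv(path)
    if "country" not in df.columns:
        raise ParseError(f"{path}: missing required column(s): country")
    return InflationInputs(rates=df.set_index("country"), us_rate=us_rate)


def write_inflation(inflation: InflationInputs, path: str | Path) -> None:
    inflation.rates.rename_axis("country").reset_index().to_csv(path, index=False)


@dataclass(frozen=True)
class CostComponentsTable:
    """Base-year cost components per user-year, keyed by (country, method).

    Components may be supplied per method only, in which case they broadcast
    to every country (stored under the wildcard country ``"*"``).
    """

    frame: pd.DataFrame  # index: (country, method); columns personnel, drugs_supplies, commodity

    def __post_init__(self) -> None:
        needed = ["personnel", "drugs_supplies", "commodity"]
        missing = [c for c in needed if c not in self.frame.columns]
        if missing:
            raise ParseError(f"cost table missing column(s): {', '.join(missing)}")
        frame = self.frame[needed].astype(float)
        if frame.index.nlevels != 2:
            raise InputError("cost table must be indexed by (country, method)")
        vals = frame.to_numpy()
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise InputError("cost components must be finite and nonnegative")
        object.__setattr__(self, "frame", frame)

    @property
    def methods(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.frame.index.get_level_values(1)))

    @property
    def is_broadcast(self) -> bool:
        return tuple(dict.fromkeys(self.frame.index.get_level_values(0))) == ("*",)

    def components(self, country: str, method: str) -> tuple[float, float, float]:
        for key in ((str(country), method), ("*", method)):
            try:
                row = self.frame.loc[key]
            except KeyError:
                continue
            return (float(row["personnel"]), float(row["drugs_supplies"]), float(row["commodity"]))
        raise InputError(f"no cost components for country {country!r}, method {method!r}")

    @classmethod
    def from_method_table(
        cls, frame: pd.DataFrame, countries: Sequence[str] | None = None
    ) -> "CostComponentsTable":
        """Build from a per-method table (``method`` index), broadcasting."""
        frame = frame.copy()
        frame.index = pd.MultiIndex.from_product([["*"], frame.index.astype(str)])
        return cls(frame=frame)


def read_costs(path: str | Path) -> CostComponentsTable:
    """Read ``country,method,personnel,drugs_supplies,commodity`` CSV; the
    ``country`` column is optional (omit it to broadcast per-method costs)."""
    df = pd.read_csv(path)
    missing = [c for c in _COST_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s): {', '.join(missing)}")
    if "country" not in df.columns:
        return CostComponentsTable.from_method_table(df.set_index("method"))
    return CostComponentsTable(frame=df.set_index(["country", "method"]))


def write_costs(costs: CostComponentsTable, path: str | Path) -> None:
    frame = costs.frame.rename_axis(["country", "method"]).reset_index()
    if costs.is_broadcast:
        frame = frame.drop(columns="country")
    frame.to_csv(path, index=False)


def cost_per_user(
    components: tuple[float, float, float],
    inflation: InflationInputs,
    country: str,
    target_year: int,
) -> float:
    """Total per-user annual cost in target-year USD: each component times
    its inflation factor, summed."""
    personnel, drugs_supplies, commodity = components
    return (
        personnel * personnel_factor(inflation.country_rates(country), target_year)
        + drugs_supplies * drugs_supplies_factor(inflation.us_rate, target_year)
        + commodity * commodity_factor(target_year)
    )


def cost_per_user_by_method(
    costs: CostComponentsTable,
    inflation: InflationInputs,
    country: str,
    target_year: int,
    methods: Sequence[str] | None = None,
) -> dict[str, float]:
    methods = list(methods) if methods is not None else list(costs.methods)
    return {
        m: cost_per_user(costs.components(country, m), inflation, country, target_year)
        for m in methods
    }


def total_cost(users_modern: float, mix: MethodMix, per_user_costs: Mapping[str, float]) -> float:
    """Scenario total direct cost in USD thousands per year:
    sum_k users_modern * mix_k * cost_k (thousands of users x USD/user)."""
    missing = [m for m in mix.methods if m not in per_user_costs]
    if missing:
        raise InputError(f"no per-user cost for method(s): {', '.join(missing)}")
    if users_modern < 0:
        raise InputError("user count must be nonnegative")
    return sum(users_modern * mix.shares[m] * per_user_costs[m] for m in mix.methods)
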