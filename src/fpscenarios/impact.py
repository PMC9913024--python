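"""Annual unintended pregnancies under a scenario.

Two groups contribute. Modern-method users experience method failure at
age-adjusted annual rates, weighted by the method mix (held constant over
time). Women with unmet need for modern methods -- traditional users plus
women using no method who want to avoid pregnancy -- become pregnant at an
annual rate whose default, 0.448, is the median of the country-specific
distribution estimated for this group; a per-country rate table may be
supplied instead. Women with no desire to avoid pregnancy do not enter
either group and are excluded by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputError, ParseError

_SHARE_TOL = 1e-9

#: Median of the country-specific pregnancy-rate distribution for women with
#: unmet need for modern methods, per woman-year.
DEFAULT_PREGNANCY_RATE = 0.448


@dataclass(frozen=True)
class MethodMix:
    """Shares of modern users by method; nonnegative, summing to 1."""

    shares: Mapping[str, float]

    def __post_init__(self) -> None:
        shares = {str(k): float(v) for k, v in dict(self.shares).items()}
        object.__setattr__(self, "shares", shares)
        if not shares:
            raise InputError("method mix is empty")
        arr = np.array(list(shares.values()))
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise InputError("method-mix shares must be finite and nonnegative")
        if abs(arr.sum() - 1.0) > _SHARE_TOL:
            raise InputError(f"method-mix shares sum to {arr.sum()!r}, expected 1")

    @property
    def methods(self) -> tuple[str, ...]:
        return tuple(self.shares)


@dataclass(frozen=True)
class FailureRateTable:
    """Annual per-user failure probability by method, each in [0, 0.5)."""

    rates: Mapping[str, float]

    def __post_init__(self) -> None:
        rates = {str(k): float(v) for k, v in dict(self.rates).items()}
        object.__setattr__(self, "rates", rates)
        arr = np.array(list(rates.values()), dtype=float)
        if arr.size and (np.any(arr < 0) or np.any(arr >= 0.5) or not np.all(np.isfinite(arr))):
            raise InputError("failure rates must lie in [0, 0.5)")


@dataclass(frozen=True)
class PregnancyRate:
    """Pregnancy rate for women with unmet need for modern methods, per
    woman-year: a scalar applied to every country, optionally overridden by
    a per-country table."""

    rate: float = DEFAULT_PREGNANCY_RATE
    by_country: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        by_country = {str(k): float(v) for k, v in dict(self.by_country).items()}
        object.__setattr__(self, "by_country", by_country)
        for label, r in [("scalar", self.rate), *by_country.items()]:
            if not np.isfinite(r) or not 0.0 < r < 1.0:
                raise InputError(f"pregnancy rate for {label} must lie in (0, 1), got {r}")

    def resolve(self, country: str | None = None) -> float:
        if country is not None and country in self.by_country:
            return self.by_country[country]
        return self.rate


def unintended_pregnancies(
    users_modern: float,
    unmet_modern: float,
    mix: MethodMix,
    failures: FailureRateTable,
    rate: PregnancyRate,
    country: str | None = None,
) -> float:
    """Annual unintended pregnancies, in thousands.

    sum_k users_modern * mix_k * failure_k + unmet_modern * rate(country);
    failure rates are annual per-user probabilities applied to the scenario's
    user counts, with no within-year dynamics, and the non-user rate is held
    constant over time.
    """
    missing = [m for m in mix.methods if m not in failures.rates]
    if missing:
        raise InputError(f"no failure rate for method(s): {', '.join(missing)}")
    if users_modern < 0 or unmet_modern < 0:
        raise InputError("user and unmet counts must be nonnegative")
    weighted_failure = sum(mix.shares[m] * failures.rates[m] for m in mix.methods)
    return users_modern * weighted_failure + unmet_modern * rate.resolve(country)


# -- CSV dialects -----------------------------------------------------------


def _read_two_column(path: str | Path, key: str, value: str) -> dict[str, float]:
    df = pd.read_csv(path)
    missing = [c for c in (key, value) if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s): {', '.join(missing)}")
    return dict(zip(df[key].astype(str), df[value].astype(float)))


def read_method_mix(path: str | Path) -> MethodMix:
    """Read ``method,share`` CSV."""
    return MethodMix(_read_two_column(path, "method", "share"))


def read_failure_rates(path: str | Path) -> FailureRateTable:
    """Read ``method,annual_failure_rate`` CSV."""
    return FailureRateTable(_read_two_column(path, "method", "annual_failure_rate"))


def read_pregnancy_rates(path: str | Path, default: float = DEFAULT_PREGNANCY_RATE) -> PregnancyRate:
    """Read optional ``country,pregnancy_rate`` CSV of per-country rates."""
    return PregnancyRate(rate=default, by_country=_read_two_column(path, "country", "pregnancy_rate"))


def write_method_mix(mix: MethodMix, path: str | Path) -> None:
    pd.DataFrame({"method": list(mix.methods), "share": [mix.shares[m] for m in mix.methods]}).to_csv(
        path, index=False
    )


def write_failure_rates(failures: FailureRateTable, path: str | Path) -> None:
    pd.DataFrame(
        {"method": list(failures.rates), "annual_failure_rate": list(failures.rates.values())}
    ).to_csv(path, index=False)
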