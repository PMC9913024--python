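"""Synthetic input bundles with the statistical structure the pipeline assumes.

The real inputs are posterior trajectory samples from a Bayesian hierarchical
joint projection model of contraceptive prevalence and unmet need, plus UN
population counts, a method mix, failure rates, cost components and IMF
inflation rates. This module emulates their *statistical structure* -- it
does not re-fit the hierarchical model or mimic any real country -- so the
pipeline can be developed and tested without downloads.

Trajectories are additive logistic-normal random walks on the 3-part
composition (modern, traditional, unmet vs. the remainder of WRA): each
country draws a baseline composition, a per-year drift on the modern
coordinate (additive log-ratio scale) and an innovation scale; correlated
Gaussian innovations accumulate on the log-ratio scale and are mapped back
to the simplex. This guarantees the simplex constraint the real joint model
satisfies, and the country-specific innovation scale reproduces the feature
that some countries carry much wider projection uncertainty than others.

One global seed fans out to independent substreams per generator, so adding
a generator does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .accounting import PopulationTable, write_population
from .costing import CostComponentsTable, InflationInputs, write_costs, write_inflation
from .errors import ConfigurationError
from .impact import (
    DEFAULT_PREGNANCY_RATE,
    FailureRateTable,
    MethodMix,
    write_failure_rates,
    write_method_mix,
)
from .trajectories import TrajectorySet, write_trajectories

#: Correlation of the logit-scale innovations (modern, traditional, unmet):
#: rising modern use tends to displace traditional use and erode unmet need.
INNOVATION_CORR = np.array(
    [
        [1.0, -0.3, -0.4],
        [-0.3, 1.0, 0.2],
        [-0.4, 0.2, 1.0],
    ]
)
_CHOL = np.linalg.cholesky(INNOVATION_CORR)

_STREAMS = ("params", "trajectories", "population", "methods", "inflation")


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one synthetic study.

    Defaults mirror the study setting: 131 low- and middle-income countries
    followed over 2019-2030 with a few hundred posterior draws each. Drift
    and noise are per-year increments on the additive log-ratio scale;
    population bounds are WRA counts in thousands.
    """

    n_countries: int = 131
    n_samples: int = 500
    years: tuple[int, int] = (2019, 2030)
    seed: int = 0
    drift_range: tuple[float, float] = (0.0, 0.04)
    noise_range: tuple[float, float] = (0.01, 0.08)
    population_range: tuple[float, float] = (200.0, 60000.0)
    n_methods: int = 8

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise ConfigurationError("n_countries must be a positive integer")
        if self.n_samples < 2:
            raise ConfigurationError("n_samples must be at least 2")
        y0, y1 = self.years
        if y1 <= y0:
            raise ConfigurationError("years must span at least 2 calendar years")
        if self.n_methods < 1:
            raise ConfigurationError("n_methods must be a positive integer")
        for name in ("drift_range", "noise_range", "population_range"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ConfigurationError(f"{name} must be finite")
            if lo > hi:
                raise ConfigurationError(f"{name} lower bound exceeds upper bound")
        if self.noise_range[0] <= 0:
            raise ConfigurationError(
                "noise_range lower bound must be > 0: every country has nonzero uncertainty"
            )
        if self.population_range[0] <= 0:
            raise ConfigurationError("population_range must be strictly positive")

    @property
    def year_list(self) -> tuple[int, ...]:
        return tuple(range(self.years[0], self.years[1] + 1))

    @property
    def country_ids(self) -> tuple[str, ...]:
        return tuple(f"C{i:03d}" for i in range(1, self.n_countries + 1))


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(stream)])


def _alr(x: np.ndarray) -> np.ndarray:
    """Additive log-ratio transform of (..., 3) compositions vs. remainder."""
    remainder = 1.0 - x.sum(axis=-1, keepdims=True)
    return np.log(x) - np.log(remainder)


def _inv_alr(z: np.ndarray) -> np.ndarray:
    """Inverse transform; the result always satisfies the simplex constraint."""
    # Subtract the rowwise max before exponentiating for numerical safety.
    m = np.maximum(z.max(axis=-1, keepdims=True), 0.0)
    e = np.exp(z - m)
    return e / (np.exp(-m) + e.sum(axis=-1, keepdims=True))


def country_parameters(config: SimulationConfig) -> pd.DataFrame:
    """Per-country latent parameters, deterministic in the seed.

    Columns: baseline proportions ``modern0``/``traditional0``/``unmet0``,
    per-year modern-coordinate ``drift`` and innovation scale ``noise``.
    Exposed so analytic (zero-noise) trajectories can be computed alongside
    the stochastic ones.
    """
    rng = _rng(config, "params")
    n = config.n_countries
    df = pd.DataFrame(
        {
            "modern0": rng.uniform(0.10, 0.55, n),
            "traditional0": rng.uniform(0.01, 0.10, n),
            "unmet0": rng.uniform(0.05, 0.25, n),
            "drift": rng.uniform(*config.drift_range, n),
            "noise": rng.uniform(*config.noise_range, n),
        },
        index=pd.Index(config.country_ids, name="country"),
    )
    return df


def drift_implied_trajectory(config: SimulationConfig) -> np.ndarray:
    """The noise-free trajectories implied by each country's drift alone:
    shape (n_countries, n_years, 3). The stochastic trajectories scatter
    around these paths."""
    params = country_parameters(config)
    x0 = params[["modern0", "traditional0", "unmet0"]].to_numpy()
    z0 = _alr(x0)
    steps = np.arange(len(config.year_list))
    drift_vec = np.zeros((config.n_countries, 1, 3))
    drift_vec[:, 0, 0] = params["drift"].to_numpy()
    z = z0[:, None, :] + steps[None, :, None] * drift_vec
    return _inv_alr(z)


def generate_trajectories(config: SimulationConfig) -> TrajectorySet:
    """Correlated logit-scale random walks mapped to the simplex.

    Year 0 equals the country baseline in every sample (the walk accumulates
    uncertainty going forward, as a projection does); identical seeds give
    identical output.
    """
    params = country_parameters(config)
    c_n, s_n = config.n_countries, config.n_samples
    years = config.year_list
    y_n = len(years)

    x0 = params[["modern0", "traditional0", "unmet0"]].to_numpy()
    z0 = _alr(x0)  # (C, 3)

    rng = _rng(config, "trajectories")
    eps = rng.standard_normal((c_n, s_n, y_n - 1, 3)) @ _CHOL.T
    drift_vec = np.zeros((c_n, 1, 1, 3))
    drift_vec[:, 0, 0, 0] = params["drift"].to_numpy()
    noise = params["noise"].to_numpy()[:, None, None, None]
    steps = drift_vec + noise * eps

    z = np.empty((c_n, s_n, y_n, 3))
    z[:, :, 0, :] = z0[:, None, :]
    z[:, :, 1:, :] = z0[:, None, None, :] + np.cumsum(steps, axis=2)
    return TrajectorySet(countries=config.country_ids, years=years, values=_inv_alr(z))


def generate_population(config: SimulationConfig) -> PopulationTable:
    """WRA counts in thousands, geometric interpolation between log-uniform
    start and end levels drawn within ``population_range`` (so every
    country-year count stays inside the range and varies smoothly)."""
    rng = _rng(config, "population")
    lo, hi = config.population_range
    n, years = config.n_countries, config.year_list
    if lo == hi:
        start = end = np.full(n, lo)
    else:
        start = np.exp(rng.uniform(np.log(lo), np.log(hi), n))
        end = np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    frac = np.linspace(0.0, 1.0, len(years))
    counts = start[:, None] * (end / start)[:, None] ** frac[None, :]
    idx = pd.MultiIndex.from_product([config.country_ids, years], names=["country", "year"])
    return PopulationTable(counts=pd.Series(counts.ravel(), index=idx, name="wra_thousands"))


def generate_method_inputs(
    config: SimulationConfig,
) -> tuple[MethodMix, FailureRateTable, CostComponentsTable]:
    """A time-invariant modern-method mix (Dirichlet shares, normalised to
    sum exactly to 1), annual failure rates, and base-year per-user cost
    components broadcast to all countries."""
    rng = _rng(config, "methods")
    k = config.n_methods
    names = [f"method_{i}" for i in range(1, k + 1)]
    shares = rng.dirichlet(np.ones(k))
    shares = shares / shares.sum()
    failures = rng.uniform(0.002, 0.15, k)
    cost_frame = pd.DataFrame(
        {
            "personnel": rng.uniform(1.0, 10.0, k),
            "drugs_supplies": rng.uniform(0.5, 5.0, k),
            "commodity": rng.uniform(0.2, 8.0, k),
        },
        index=pd.Index(names, name="method"),
    )
    return (
        MethodMix(dict(zip(names, shares))),
        FailureRateTable(dict(zip(names, failures))),
        CostComponentsTable.from_method_table(cost_frame),
    )


def generate_inflation_inputs(config: SimulationConfig) -> InflationInputs:
    """Country GDP-deflator rates for 2021-2024 (each in (-0.05, 0.25)) and
    one US rate in (0, 0.15) standing for the 2015-2019 average."""
    rng = _rng(config, "inflation")
    rates = pd.DataFrame(
        rng.uniform(0.01, 0.12, (config.n_countries, 4)),
        index=pd.Index(config.country_ids, name="country"),
        columns=[f"rate_{y}" for y in (2021, 2022, 2023, 2024)],
    )
    us_rate = float(rng.uniform(0.015, 0.025))
    return InflationInputs(rates=rates, us_rate=us_rate)


def write_bundle(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete, self-consistent input bundle plus a run.config that
    reproduces the study defaults (current@50 vs accelerated@90, pregnancy
    rate 0.448). Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traj = generate_trajectories(config)
    pop = generate_population(config)
    mix, failures, costs = generate_method_inputs(config)
    inflation = generate_inflation_inputs(config)

    paths = {
        "trajectories": outdir / "trajectories.csv",
        "population": outdir / "population.csv",
        "method_mix": outdir / "method_mix.csv",
        "failure_rates": outdir / "failure_rates.csv",
        "costs": outdir / "costs.csv",
        "inflation": outdir / "inflation.csv",
        "config": outdir / "run.config",
    }
    write_trajectories(traj, paths["trajectories"])
    write_population(pop, paths["population"])
    write_method_mix(mix, paths["method_mix"])
    write_failure_rates(failures, paths["failure_rates"])
    write_costs(costs, paths["costs"])
    write_inflation(inflation, paths["inflation"])
    paths["config"].write_text(
        "\n".join(
            [
                "trajectories = trajectories.csv",
                "population = population.csv",
                "method_mix = method_mix.csv",
                "failure_rates = failure_rates.csv",
                "costs = costs.csv",
                "inflation = inflation.csv",
                f"us_rate = {inflation.us_rate!r}",
                f"pregnancy_rate = {DEFAULT_PREGNANCY_RATE}",
                f"baseline_year = {config.years[0]}",
                f"target_year = {config.years[1]}",
                "scenarios = current:50,accelerated:90",
                "",
            ]
        )
    )
    return paths
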