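"""End-to-end orchestration: config file, input loading, pipeline run, report.

A run consumes six CSV inputs (trajectories, population, method mix, failure
rates, cost components, inflation rates) plus a handful of scalars, builds
each scenario for every country (proportions -> absolute numbers ->
unintended pregnancies -> direct costs), writes the country-level results
CSV, and aggregates the scenarios into the side-by-side comparison with a
difference column. Outputs are deterministic functions of the inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import accounting, costing, impact, trajectories
from .accounting import (
    AggregateRow,
    CountryScenarioResult,
    PopulationTable,
    ScenarioComparison,
    aggregate,
    compare,
)
from .costing import CostComponentsTable, InflationInputs
from .errors import ConfigurationError, InputError
from .impact import FailureRateTable, MethodMix, PregnancyRate
from .trajectories import ScenarioSpec, TrajectorySet

log = logging.getLogger(__name__)

_PATH_KEYS = (
    "trajectories",
    "population",
    "method_mix",
    "failure_rates",
    "costs",
    "inflation",
    "pregnancy_rates",
)


@dataclass(frozen=True)
class RunConfig:
    """Paths and scalars for one pipeline run. Defaults mirror the study
    setup: scenarios current@50 and accelerated@90 over 2019->2030, scalar
    pregnancy rate 0.448 for the unmet-for-modern group."""

    trajectories: Path
    population: Path
    method_mix: Path
    failure_rates: Path
    costs: Path
    inflation: Path
    us_rate: float
    pregnancy_rates: Path | None = None
    pregnancy_rate: float = impact.DEFAULT_PREGNANCY_RATE
    baseline_year: int = 2019
    target_year: int = 2030
    scenario_percentiles: tuple[tuple[str, float], ...] = (("current", 50.0), ("accelerated", 90.0))
    report_sigfigs: int = 3
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.scenario_percentiles:
            raise ConfigurationError("at least one scenario is required")
        if self.report_sigfigs < 1:
            raise ConfigurationError("report_sigfigs must be >= 1")

    @property
    def scenarios(self) -> tuple[ScenarioSpec, ...]:
        return tuple(
            ScenarioSpec(name, pct, self.baseline_year, self.target_year)
            for name, pct in self.scenario_percentiles
        )


def parse_percentiles(text: str) -> tuple[tuple[str, float], ...]:
    """Parse ``"current:50,accelerated:90"`` (or bare ``"50,90"``, named
    ``p50``/``p90``) into (name, percentile) pairs."""
    out = []
    for piece in text.split(","):
        piece = piece.strip()
        if not piece:
            continue
        if ":" in piece:
            name, _, pct = piece.partition(":")
        else:
            name, pct = f"p{piece}", piece
        try:
            out.append((name.strip(), float(pct)))
        except ValueError:
            raise ConfigurationError(f"cannot parse scenario percentile {piece!r}") from None
    if not out:
        raise ConfigurationError("no scenarios given")
    return tuple(out)


def read_run_config(path: str | Path) -> RunConfig:
    """Read a flat ``key = value`` config file; '#' starts a comment and
    relative paths resolve against the config file's directory."""
    path = Path(path)
    pairs: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        pairs[key.strip()] = value.strip()

    required = ("trajectories", "population", "method_mix", "failure_rates", "costs", "inflation", "us_rate")
    missing = [k for k in required if k not in pairs]
    if missing:
        raise ConfigurationError(f"{path}: missing required key(s): {', '.join(missing)}")

    base = path.parent
    kwargs: dict = {}
    for key in _PATH_KEYS:
        if key in pairs:
            kwargs[key] = base / pairs[key]
    kwargs["us_rate"] = float(pairs["us_rate"])
    if "pregnancy_rate" in pairs:
        kwargs["pregnancy_rate"] = float(pairs["pregnancy_rate"])
    if "baseline_year" in pairs:
        kwargs["baseline_year"] = int(pairs["baseline_year"])
    if "target_year" in pairs:
        kwargs["target_year"] = int(pairs["target_year"])
    if "scenarios" in pairs:
        kwargs["scenario_percentiles"] = parse_percentiles(pairs["scenarios"])
    if "report_sigfigs" in pairs:
        kwargs["report_sigfigs"] = int(pairs["report_sigfigs"])
    if "log_level" in pairs:
        kwargs["log_level"] = pairs["log_level"]
    return RunConfig(**kwargs)


@dataclass(frozen=True)
class Inputs:
    """All loaded pipeline inputs."""

    trajectories: TrajectorySet
    population: PopulationTable
    mix: MethodMix
    failures: FailureRateTable
    costs: CostComponentsTable
    inflation: InflationInputs
    pregnancy_rate: PregnancyRate


def load_inputs(config: RunConfig) -> Inputs:
    traj = trajectories.read_trajectories(config.trajectories)
    pop = accounting.read_population(config.population)
    mix = impact.read_method_mix(config.method_mix)
    failures = impact.read_failure_rates(config.failure_rates)
    costs = costing.read_costs(config.costs)
    inflation = costing.read_inflation(config.inflation, us_rate=config.us_rate)
    if config.pregnancy_rates is not None:
        rate = impact.read_pregnancy_rates(config.pregnancy_rates, default=config.pregnancy_rate)
    else:
        rate = PregnancyRate(rate=config.pregnancy_rate)
    inputs = Inputs(traj, pop, mix, failures, costs, inflation, rate)
    validate_inputs(inputs)
    return inputs


def validate_inputs(inputs: Inputs) -> None:
    """Check mutual consistency: shared country sets and aligned method keys."""
    traj_countries = set(inputs.trajectories.countries)
    for name, other in (
        ("population", set(inputs.population.countries)),
        ("inflation", set(inputs.inflation.countries)),
    ):
        if other != traj_countries:
            diff = sorted(traj_countries.symmetric_difference(other))
            raise InputError(
                f"country sets of trajectories and {name} differ: {', '.join(map(str, diff))}"
            )
    if not inputs.costs.is_broadcast:
        cost_countries = set(inputs.costs.frame.index.get_level_values(0)) - {"*"}
        missing = sorted(traj_countries - cost_countries)
        if missing:
            raise InputError(f"no cost components for country(ies): {', '.join(missing)}")
    mix_methods = set(inputs.mix.methods)
    for name, keys in (
        ("failure rates", set(inputs.failures.rates)),
        ("costs", set(inputs.costs.methods)),
    ):
        missing_keys = sorted(mix_methods - keys)
        if missing_keys:
            raise InputError(f"method(s) in mix without {name}: {', '.join(missing_keys)}")


def run_scenario(inputs: Inputs, spec: ScenarioSpec) -> list[CountryScenarioResult]:
    """Build one scenario for every country in the trajectory set."""
    results = []
    for country in inputs.trajectories.countries:
        props = trajectories.scenario_proportions(inputs.trajectories, country, spec)
        users, unmet = accounting.absolute_numbers(props, inputs.population)
        pregnancies = impact.unintended_pregnancies(
            users, unmet, inputs.mix, inputs.failures, inputs.pregnancy_rate, country
        )
        per_user = costing.cost_per_user_by_method(
            inputs.costs, inputs.inflation, country, spec.target_year, inputs.mix.methods
        )
        cost = costing.total_cost(users, inputs.mix, per_user)
        log.info(
            "country=%s scenario=%s ds=%.4f users=%.1f unmet=%.1f up=%.1f cost=%.1f clipped=%s",
            country, spec.name, props.demand_satisfied, users, unmet, pregnancies, cost,
            props.clipped,
        )
        results.append(
            CountryScenarioResult(
                country=country,
                scenario=spec.name,
                demand_satisfied=props.demand_satisfied,
                users_modern=users,
                unmet_modern=unmet,
                unintended_pregnancies=pregnancies,
                total_cost=cost,
            )
        )
    return results


def run(config: RunConfig, outdir: str | Path | None = None) -> tuple[ScenarioComparison, pd.DataFrame]:
    """Run the full pipeline.

    Returns the scenario comparison and the country-level results table; if
    ``outdir`` is given, writes ``country_results.csv``, ``comparison.csv``
    and a rendered ``comparison.txt`` there.
    """
    inputs = load_inputs(config)
    all_results: list[CountryScenarioResult] = []
    rows: list[AggregateRow] = []
    for spec in config.scenarios:
        results = run_scenario(inputs, spec)
        all_results.extend(results)
        rows.append(aggregate(results))
    if len(rows) >= 2:
        comparison = compare(rows[0], rows[-1]) if len(rows) == 2 else ScenarioComparison(tuple(rows))
    else:
        comparison = ScenarioComparison(tuple(rows))
    country_table = accounting.results_to_frame(all_results)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        country_table.to_csv(outdir / "country_results.csv", index=False)
        comparison.to_frame().to_csv(outdir / "comparison.csv")
        (outdir / "comparison.txt").write_text(comparison.render(config.report_sigfigs) + "\n")
    return comparison, country_table


def count_below_threshold(
    country_rows: pd.DataFrame, threshold: float, scenario: str | None = None
) -> int:
    """Number of countries whose demand satisfied is strictly below
    ``threshold`` percent. ``country_rows`` is a country-level results table
    (one scenario, or pass ``scenario`` to select one)."""
    df = country_rows
    if scenario is not None:
        df = df[df["scenario"] == scenario]
    elif "scenario" in df.columns and df["scenario"].nunique() > 1:
        raise InputError("country table mixes scenarios; pass scenario= to select one")
    return int((df["demand_satisfied"] * 100.0 < threshold).sum())


def comparison_from_results(country_rows: pd.DataFrame) -> ScenarioComparison:
    """Re-aggregate a country-level results table into a scenario comparison
    (scenario order = order of first appearance)."""
    order = list(dict.fromkeys(country_rows["scenario"]))
    rows = []
    for name in order:
        sub = country_rows[country_rows["scenario"] == name]
        results = [
            CountryScenarioResult(
                country=str(r.country),
                scenario=name,
                demand_satisfied=float(r.demand_satisfied),
                users_modern=float(r.users_modern_thousands),
                unmet_modern=float(r.unmet_modern_thousands),
                unintended_pregnancies=float(r.unintended_pregnancies_thousands),
                total_cost=float(r.total_cost_usd_thousands),
            )
            for r in sub.itertuples()
        ]
        rows.append(aggregate(results))
    if len(rows) == 2:
        return compare(rows[0], rows[1])
    return ScenarioComparison(tuple(rows))
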