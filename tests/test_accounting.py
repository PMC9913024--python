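"""Absolute-number accounting, aggregation and the scenario comparison."""

import numpy as np
import pandas as pd
import pytest

import fpscenarios as fp
from fpscenarios.accounting import QUANTITY_ROWS
from fpscenarios.errors import InputError, InvariantError


def make_result(country, scenario, users, unmet, up=0.0, cost=0.0):
    total = users + unmet
    return fp.CountryScenarioResult(
        country=country,
        scenario=scenario,
        demand_satisfied=users / total if total else 0.0,
        users_modern=users,
        unmet_modern=unmet,
        unintended_pregnancies=up,
        total_cost=cost,
    )


class TestAbsoluteNumbers:
    def test_proportions_times_population(self):
        props = fp.CountryScenarioProportions(
            country="A", target_year=2030, demand_satisfied=5 / 7,
            modern=0.5, trad_plus_unmet=0.2, total_demand=0.7,
        )
        pop = fp.PopulationTable(
            counts=pd.Series([1000.0], index=pd.MultiIndex.from_tuples([("A", 2030)]))
        )
        users, unmet = fp.absolute_numbers(props, pop)
        assert users == pytest.approx(500.0)
        assert unmet == pytest.approx(200.0)
        assert users / (users + unmet) == pytest.approx(props.demand_satisfied, abs=1e-12)

    def test_zero_population_rejected(self):
        with pytest.raises(InputError):
            fp.PopulationTable(
                counts=pd.Series([0.0], index=pd.MultiIndex.from_tuples([("A", 2030)]))
            )

    def test_missing_population_names_country_year(self):
        props = fp.CountryScenarioProportions("B", 2030, 0.5, 0.25, 0.25, 0.5)
        pop = fp.PopulationTable(
            counts=pd.Series([10.0], index=pd.MultiIndex.from_tuples([("A", 2030)]))
        )
        with pytest.raises(InputError, match="'B'.*2030"):
            fp.absolute_numbers(props, pop)


class TestAggregate:
    @pytest.mark.parametrize(
        "users,unmet,expected_pct",
        [
            (783_000.0, 218_000.0, 78),  # published current-progress aggregate
            (876_000.0, 177_000.0, 83),  # published accelerated aggregate
        ],
    )
    def test_percent_is_ratio_of_sums(self, users, unmet, expected_pct):
        # Split arbitrarily over two countries: only the sums matter.
        row = fp.aggregate(
            [
                make_result("A", "s", users * 0.3, unmet * 0.6),
                make_result("B", "s", users * 0.7, unmet * 0.4),
            ]
        )
        assert round(row.percent_demand_satisfied) == expected_pct

    def test_single_country_passthrough(self):
        r = make_result("A", "s", 100.0, 25.0, up=7.0, cost=500.0)
        row = fp.aggregate([r])
        assert row.users_modern == r.users_modern
        assert row.unmet_modern == r.unmet_modern
        assert row.unintended_pregnancies == r.unintended_pregnancies
        assert row.total_cost == r.total_cost

    def test_duplicate_country_rejected(self):
        with pytest.raises(InputError, match="duplicate"):
            fp.aggregate([make_result("A", "s", 1, 1), make_result("A", "s", 2, 1)])

    def test_permutation_invariant_and_additive(self):
        rng = np.random.default_rng(0)
        results = [
            make_result(f"C{i}", "s", *rng.uniform(10, 1000, 2), up=rng.uniform(0, 50),
                        cost=rng.uniform(0, 5000))
            for i in range(8)
        ]
        full = fp.aggregate(results)
        shuffled = fp.aggregate(results[::-1])
        assert full == shuffled
        part_a, part_b = fp.aggregate(results[:3]), fp.aggregate(results[3:])
        assert part_a.users_modern + part_b.users_modern == pytest.approx(full.users_modern)
        assert part_a.total_cost + part_b.total_cost == pytest.approx(full.total_cost)

    def test_aggregate_ds_between_country_extremes(self):
        rng = np.random.default_rng(1)
        results = [make_result(f"C{i}", "s", *rng.uniform(10, 1000, 2)) for i in range(10)]
        agg_pct = fp.aggregate(results).percent_demand_satisfied
        pcts = [100 * r.demand_satisfied for r in results]
        assert min(pcts) <= agg_pct <= max(pcts)


class TestCompare:
    def _published_rows(self):
        current = fp.AggregateRow(
            "current", ("all",), users_modern=783_000.0, unmet_modern=218_000.0,
            unintended_pregnancies=97_000.0, total_cost=3_990_000.0,
        )
        accelerated = fp.AggregateRow(
            "accelerated", ("all",), users_modern=876_000.0, unmet_modern=177_000.0,
            unintended_pregnancies=83_100.0, total_cost=4_470_000.0,
        )
        return current, accelerated

    def test_published_difference_column(self):
        comparison = fp.compare(*self._published_rows())
        diff = comparison.to_frame()["difference"]
        assert diff[QUANTITY_ROWS[1]] == pytest.approx(93_000.0)   # more users
        assert diff[QUANTITY_ROWS[2]] == pytest.approx(-41_000.0)  # fewer unmet
        assert diff[QUANTITY_ROWS[3]] == pytest.approx(-13_900.0)  # fewer pregnancies
        assert diff[QUANTITY_ROWS[4]] == pytest.approx(480_000.0)  # extra cost
        assert round(diff[QUANTITY_ROWS[0]]) == 5  # percentage points, unrounded then rounded

    def test_identical_rows_zero_difference(self):
        row = fp.AggregateRow("s", ("A",), 10.0, 5.0, 1.0, 100.0)
        comparison = fp.ScenarioComparison((row, fp.AggregateRow("t", ("A",), 10.0, 5.0, 1.0, 100.0)))
        assert (comparison.to_frame()["difference"] == 0).all()

    def test_mismatched_country_sets_listed(self):
        cur = fp.AggregateRow("current", ("A", "B"), 1, 1, 0, 0)
        acc = fp.AggregateRow("accelerated", ("A", "C"), 1, 1, 0, 0)
        with pytest.raises(InputError, match="B, C"):
            fp.compare(cur, acc)

    def test_render_rounds_to_sigfigs(self):
        comparison = fp.compare(*self._published_rows())
        text = comparison.render(sigfigs=3)
        assert "78%" in text and "83%" in text and "5%" in text
        assert "783,000" in text and "876,000" in text and "93,000" in text
        assert "-13,900" in text


class TestResultInvariants:
    def test_inconsistent_ds_rejected(self):
        with pytest.raises(InvariantError):
            fp.CountryScenarioResult(
                country="A", scenario="s", demand_satisfied=0.9,
                users_modern=100.0, unmet_modern=100.0,
                unintended_pregnancies=0.0, total_cost=0.0,
            )

    def test_results_csv_round_trip(self, tmp_path):
        results = [make_result("A", "current", 100.0, 30.0, 12.0, 550.0),
                   make_result("B", "current", 70.0, 60.0, 28.0, 320.0)]
        path = tmp_path / "results.csv"
        fp.write_results(results, path)
        df = fp.read_results(path)
        assert list(df["country"]) == ["A", "B"]
        assert df["users_modern_thousands"].tolist() == [100.0, 70.0]


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected",
        [(96_953.2, 97_000.0), (83_112.0, 83_100.0), (13_851.0, 13_900.0), (0.0, 0.0),
         (-41_042.0, -41_000.0), (0.004361, 0.00436)],
    )
    def test_three_sigfigs(self, x, expected):
        assert fp.round_sigfigs(x, 3) == pytest.approx(expected)
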