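"""Demand-satisfied arithmetic, quantile rule, and scenario construction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fpscenarios as fp
from fpscenarios.errors import InputError, ParseError


def quantile_oracle(values, p):
    """Brute force: sort, then linearly interpolate between order statistics."""
    v = sorted(values)
    h = (len(v) - 1) * p / 100.0
    lo = math.floor(h)
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


class TestDemandSatisfied:
    @pytest.mark.parametrize(
        "modern,traditional,unmet,expected",
        [
            (0.30, 0.10, 0.10, 0.60),
            (0.0, 0.0, 0.0, 0.0),  # zero-demand convention
            (0.5, 0.0, 0.0, 1.0),
            (0.25, 0.25, 0.25, 1 / 3),
        ],
    )
    def test_examples(self, modern, traditional, unmet, expected):
        assert fp.demand_satisfied(modern, traditional, unmet) == pytest.approx(expected)

    def test_vectorized(self):
        ds = fp.demand_satisfied([0.3, 0.0], [0.1, 0.0], [0.1, 0.0])
        np.testing.assert_allclose(ds, [0.6, 0.0])

    def test_off_simplex_rejected(self):
        with pytest.raises(InputError):
            fp.demand_satisfied(0.6, 0.3, 0.3)
        with pytest.raises(InputError):
            fp.demand_satisfied(1.2, 0.0, 0.0)


class TestQuantile:
    @pytest.mark.parametrize(
        "values,p,expected",
        [
            ([1, 2, 3], 50, 2.0),  # odd length -> middle order statistic
            (list(range(11)), 90, 9.0),  # linear interpolation, evenly spaced
            ([5.0, 1.0], 0, 1.0),
            ([5.0, 1.0], 100, 5.0),
            ([3.0, 1.0], 25, 1.5),
        ],
    )
    def test_examples(self, values, p, expected):
        assert fp.quantile(values, p) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=300, deadline=None)
    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=12, unique=True),
        st.floats(0.0, 100.0),
    )
    def test_matches_bruteforce_oracle(self, values, p):
        assert fp.quantile(values, p) == pytest.approx(quantile_oracle(values, p), abs=1e-9)

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(InputError):
            fp.quantile([], 50)
        with pytest.raises(InputError):
            fp.quantile([1.0, float("nan")], 50)


class TestChangeDistribution:
    def test_identical_samples_give_constant_change(self):
        values = np.tile(
            np.array([[[0.25, 0.15, 0.10], [0.36, 0.12, 0.12]]]), (1, 4, 1, 1)
        )  # DS: 0.5 -> 0.6 in every sample
        traj = fp.TrajectorySet(("X",), (2019, 2030), values)
        changes = fp.change_distribution(traj, "X", fp.CURRENT_PROGRESS)
        np.testing.assert_allclose(changes, 0.1, atol=1e-12)

    def test_no_change_gives_zeros(self, small_trajectories):
        traj = small_trajectories
        frozen = traj.values.copy()
        frozen[:, :, -1, :] = frozen[:, :, 0, :]
        t2 = fp.TrajectorySet(traj.countries, traj.years, frozen)
        for country in t2.countries:
            np.testing.assert_allclose(
                fp.change_distribution(t2, country, fp.CURRENT_PROGRESS), 0.0, atol=1e-15
            )

    def test_mean_matches_per_sample_loop_oracle(self, small_trajectories):
        traj = small_trajectories
        spec = fp.CURRENT_PROGRESS
        for country in traj.countries:
            ci = traj.countries.index(country)
            expected = []
            for s in range(traj.n_samples):
                m0, t0, u0 = traj.values[ci, s, 0, :]
                m1, t1, u1 = traj.values[ci, s, -1, :]
                expected.append(m1 / (m1 + t1 + u1) - m0 / (m0 + t0 + u0))
            got = fp.change_distribution(traj, country, spec)
            assert np.mean(got) == pytest.approx(np.mean(expected), abs=1e-12)

    def test_missing_country_and_year(self, small_trajectories):
        with pytest.raises(InputError):
            fp.change_distribution(small_trajectories, "nowhere", fp.CURRENT_PROGRESS)
        with pytest.raises(InputError):
            fp.change_distribution(
                small_trajectories, "C001", fp.ScenarioSpec("x", 50, 1990, 2030)
            )


class TestScenarioProportions:
    def test_hand_computed_three_sample_oracle(self, hand_trajectory_set):
        # Baseline DS: (0.6, 0.5, 0.8), median 0.6.
        # Changes: (0.2, 0.1, 0.45/0.55 - 0.8); target total demand (0.5, 0.5, 0.55).
        changes = sorted([0.2, 0.1, 0.45 / 0.55 - 0.8])
        p50 = fp.scenario_proportions(hand_trajectory_set, "C001", fp.CURRENT_PROGRESS)
        assert p50.demand_satisfied == pytest.approx(0.6 + changes[1], abs=1e-12)
        assert p50.total_demand == pytest.approx(0.5, abs=1e-12)
        assert p50.modern == pytest.approx((0.6 + changes[1]) * 0.5, abs=1e-12)

        p90 = fp.scenario_proportions(hand_trajectory_set, "C001", fp.ACCELERATED_PROGRESS)
        q90 = changes[1] + 0.8 * (changes[2] - changes[1])
        assert p90.demand_satisfied == pytest.approx(0.6 + q90, abs=1e-12)
        assert p90.trad_plus_unmet == pytest.approx(0.5 - (0.6 + q90) * 0.5, abs=1e-12)

    def test_monotone_in_percentile(self, small_trajectories):
        for country in small_trajectories.countries:
            ds = [
                fp.scenario_proportions(
                    small_trajectories, country, fp.ScenarioSpec(f"p{p}", p)
                ).demand_satisfied
                for p in (10, 25, 50, 75, 90)
            ]
            assert ds == sorted(ds)

    def test_accounting_identity(self, small_trajectories):
        for country in small_trajectories.countries:
            for spec in (fp.CURRENT_PROGRESS, fp.ACCELERATED_PROGRESS):
                props = fp.scenario_proportions(small_trajectories, country, spec)
                assert props.modern + props.trad_plus_unmet == pytest.approx(
                    props.total_demand, abs=1e-12
                )
                assert 0.0 <= props.demand_satisfied <= 1.0

    def test_degenerate_trajectories_percentile_independent(self):
        values = np.tile(np.array([[[0.3, 0.1, 0.1], [0.42, 0.09, 0.09]]]), (1, 5, 1, 1))
        traj = fp.TrajectorySet(("X",), (2019, 2030), values)
        ds = {
            p: fp.scenario_proportions(traj, "X", fp.ScenarioSpec(f"p{p}", p)).demand_satisfied
            for p in (5, 50, 95)
        }
        assert ds[5] == pytest.approx(ds[50], abs=1e-12)
        assert ds[95] == pytest.approx(ds[50], abs=1e-12)
        assert ds[50] == pytest.approx(0.42 / 0.60, abs=1e-12)

    def test_clipping_flagged(self):
        # Median baseline DS plus a large change quantile exceeds 1: clip + flag.
        values = np.array(
            [
                [
                    [[0.90, 0.03, 0.02], [0.90, 0.03, 0.02]],
                    [[0.10, 0.40, 0.40], [0.85, 0.05, 0.05]],
                    [[0.50, 0.20, 0.20], [0.88, 0.04, 0.04]],
                ]
            ]
        )
        traj = fp.TrajectorySet(("X",), (2019, 2030), values)
        props = fp.scenario_proportions(traj, "X", fp.ACCELERATED_PROGRESS)
        assert props.clipped
        assert props.demand_satisfied == 1.0


class TestTrajectoryIO:
    def test_round_trip(self, small_trajectories, tmp_path):
        path = tmp_path / "traj.csv"
        fp.write_trajectories(small_trajectories, path)
        assert fp.read_trajectories(path) == small_trajectories

    def test_missing_sample_column_named(self, small_trajectories, tmp_path):
        path = tmp_path / "traj.csv"
        df = small_trajectories.to_frame().drop(columns="sample")
        df.to_csv(path, index=False)
        with pytest.raises(ParseError, match="sample"):
            fp.read_trajectories(path)

    def test_hand_written_literals(self, tmp_path):
        path = tmp_path / "tiny.csv"
        path.write_text(
            "country,sample,year,modern,traditional,unmet\n"
            "A,0,2019,0.30,0.10,0.10\n"
            "A,0,2030,0.40,0.05,0.05\n"
            "A,1,2019,0.20,0.10,0.10\n"
            "A,1,2030,0.30,0.10,0.10\n"
        )
        traj = fp.read_trajectories(path)
        assert traj.countries == ("A",)
        assert traj.years == (2019, 2030)
        np.testing.assert_allclose(traj.values[0, 0, 1], [0.40, 0.05, 0.05])
        np.testing.assert_allclose(traj.values[0, 1, 0], [0.20, 0.10, 0.10])

    def test_malformed_row_reported_with_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "country,sample,year,modern,traditional,unmet\n"
            "A,0,2019,0.30,0.10,0.10\n"
            "A,0,2030,0.90,0.50,0.10\n"  # off-simplex, line 3
            "A,1,2019,0.20,0.10,0.10\n"
            "A,1,2030,0.30,0.10,0.10\n"
        )
        with pytest.raises(ParseError, match="3"):
            fp.read_trajectories(path)

    def test_gap_in_grid_rejected(self, tmp_path):
        path = tmp_path / "gap.csv"
        path.write_text(
            "country,sample,year,modern,traditional,unmet\n"
            "A,0,2019,0.30,0.10,0.10\n"
            "A,0,2030,0.40,0.05,0.05\n"
            "A,1,2019,0.20,0.10,0.10\n"
        )
        with pytest.raises(ParseError, match="gap"):
            fp.read_trajectories(path)
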