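"""Landings-to-effort extrapolation and depth-restriction simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trossa import reference
from trossa.errors import DomainError
from trossa.rates import RateTable
from trossa.scenarios import (
    EffortProfile,
    LandingsSeries,
    ScenarioConstants,
    effort_from_landings,
    extrapolate_bycatch,
    extrapolate_catch_tons,
    landings_to_fish,
    rate_table_with_unrounded_birds,
    redistribute_effort,
    scenario_table,
    simulate_restriction,
    unrounded_bird_rates,
)

MEAN_TONS = reference.MEAN_ANNUAL_LANDINGS_TONS  # 5386.8


@pytest.fixture
def mean_year_effort(ref_table):
    return effort_from_landings(MEAN_TONS, ref_table)


@pytest.fixture
def unrounded(ref_table):
    return rate_table_with_unrounded_birds(ref_table, MEAN_TONS)


@pytest.mark.parametrize("tons,w,fish", [(3, 3, 1000), (0, 3, 0), (4516, 3, 1_505_333)])
def test_landings_to_fish(tons, w, fish):
    assert round(landings_to_fish(tons, w)) == fish


def test_landings_to_fish_rejects_bad_weight():
    with pytest.raises(DomainError):
        landings_to_fish(10, 0)


class TestEffortFromLandings:
    def test_shallowest_bin_matches_hand_computation(self, mean_year_effort):
        # tons × proportion × 1000 / 3 kg / catch rate
        expected = MEAN_TONS * 0.13 * 1000 / 3 / 43.03
        assert mean_year_effort.effort[0] == pytest.approx(expected, rel=1e-12)
        assert mean_year_effort.effort[0] == pytest.approx(5425, abs=1)

    def test_single_bin_closed_form(self):
        table = RateTable(
            edges=[0.0], fish_rate=[20.0], bird_rate=[0.1], mammal_rate=[0.0],
            landings_proportion=[1.0],
        )
        eff = effort_from_landings(600.0, table)
        assert eff.effort[0] == pytest.approx(600 * 1000 / 3 / 20)

    def test_linearity_in_tonnage(self, ref_table):
        one = effort_from_landings(1000.0, ref_table)
        two = effort_from_landings(2000.0, ref_table)
        np.testing.assert_allclose(two.effort, 2 * one.effort, rtol=1e-12)

    def test_zero_rate_with_positive_share_is_error(self):
        table = RateTable(
            edges=[0.0, 10.0], fish_rate=[0.0, 20.0], bird_rate=[0, 0],
            mammal_rate=[0, 0], landings_proportion=[0.5, 0.5],
        )
        with pytest.raises(DomainError, match="effort undefined"):
            effort_from_landings(100.0, table)


class TestUnroundedRates:
    def test_recovers_full_precision_rates(self, ref_table, mean_year_effort):
        table = unrounded_bird_rates(
            ref_table, reference.ANNUAL_SEABIRD_BYCATCH, mean_year_effort
        )
        assert table.bird_rate[1] == pytest.approx(0.1896, abs=2e-4)  # printed 0.19
        assert table.bird_rate[4] == pytest.approx(0.0122, abs=2e-4)  # printed 0.01
        assert table.bird_rate[5] == 0.0

    def test_rounding_to_two_decimals_reproduces_printed_column(self, unrounded):
        np.testing.assert_allclose(
            np.round(unrounded.bird_rate, 2), reference.SEABIRD_BYCATCH_RATE
        )


class TestExtrapolation:
    def test_baseline_total_equals_sum_of_bycatch_column(self, mean_year_effort, unrounded):
        per_bin, total = extrapolate_bycatch(mean_year_effort, unrounded)
        np.testing.assert_allclose(per_bin, reference.ANNUAL_SEABIRD_BYCATCH, atol=1e-6)
        assert total == pytest.approx(6572.0, abs=1e-6)

    def test_zero_effort_zero_bycatch(self, ref_table):
        eff = EffortProfile(edges=ref_table.edges, effort=np.zeros(6))
        assert extrapolate_bycatch(eff, ref_table)[1] == 0.0

    def test_uniform_rate_depends_only_on_total_effort(self):
        table = RateTable(edges=[0, 10, 20], fish_rate=[1, 1, 1],
                          bird_rate=[0.3, 0.3, 0.3], mammal_rate=[0, 0, 0])
        for split in ([60, 30, 10], [10, 30, 60], [100, 0, 0]):
            eff = EffortProfile(edges=table.edges, effort=np.array(split, float))
            assert extrapolate_bycatch(eff, table)[1] == pytest.approx(0.3 * 100)


class TestSimulateRestriction:
    def test_no_restriction_is_exact_baseline(self, mean_year_effort, unrounded):
        res = simulate_restriction(mean_year_effort, unrounded, 0.0)
        assert res.projected_bird_bycatch == pytest.approx(6572.0, abs=1e-9)
        assert res.projected_catch_tons == pytest.approx(MEAN_TONS, abs=1e-9)
        assert res.delta_catch == 0.0 and res.delta_birds == 0.0 and res.delta_mammals == 0.0

    def test_deepest_restriction_closed_form(self, mean_year_effort, unrounded):
        res = simulate_restriction(mean_year_effort, unrounded, 50.0)
        expected = mean_year_effort.total * 39.76 * 3 / 1000
        assert res.projected_catch_tons == pytest.approx(expected, rel=1e-12)
        assert res.projected_catch_tons == pytest.approx(5996, abs=2)
        assert res.projected_bird_bycatch == 0.0

    def test_ten_metre_restriction_matches_published_projection(
        self, mean_year_effort, unrounded
    ):
        res = simulate_restriction(mean_year_effort, unrounded, 10.0)
        assert res.projected_bird_bycatch == pytest.approx(4876, abs=3)
        assert res.projected_catch_tons == pytest.approx(5252, abs=2)

    def test_equal_shares_differs_from_proportional(self, mean_year_effort, unrounded):
        prop = simulate_restriction(
            mean_year_effort, unrounded, 10.0,
            ScenarioConstants(redistribution="proportional"),
        )
        # independent closed-form check: proportional reallocation inflates all
        # open bins by the same factor, so bycatch scales by total/open-total
        open_eff = mean_year_effort.effort[1:]
        factor = mean_year_effort.total / open_eff.sum()
        expected = (open_eff * unrounded.bird_rate[1:]).sum() * factor
        assert prop.projected_bird_bycatch == pytest.approx(expected, rel=1e-12)
        assert prop.projected_bird_bycatch == pytest.approx(5050, abs=3)

    def test_restriction_off_bin_edge_rejected(self, mean_year_effort, unrounded):
        with pytest.raises(DomainError, match="bin edge"):
            simulate_restriction(mean_year_effort, unrounded, 15.0)

    def test_closing_every_bin_rejected(self, mean_year_effort, unrounded):
        with pytest.raises(DomainError):
            redistribute_effort(mean_year_effort, 60.0)

    def test_monotone_bycatch_under_nonincreasing_rates(self, mean_year_effort, unrounded):
        """Bird rates fall with depth, so bycatch falls as the closure deepens."""
        totals = [
            simulate_restriction(mean_year_effort, unrounded, d).projected_bird_bycatch
            for d in (0, 10, 20, 30, 40, 50)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(totals, totals[1:]))

    def test_flat_fish_rate_makes_catch_invariant(self, mean_year_effort, unrounded):
        flat = unrounded.replace(fish_rate=np.full(6, 35.0))
        catches = {
            simulate_restriction(mean_year_effort, flat, d).projected_catch_tons
            for d in (0, 10, 30, 50)
        }
        assert max(catches) - min(catches) < 1e-9


@settings(derandomize=True, max_examples=100)
@given(
    effort=st.lists(st.floats(0, 1e5), min_size=6, max_size=6),
    k=st.integers(1, 5),
    proportional=st.booleans(),
)
def test_redistribution_conserves_effort(effort, k, proportional):
    eff = EffortProfile(edges=reference.DEPTH_BIN_EDGES, effort=np.array(effort))
    out = redistribute_effort(
        eff, float(reference.DEPTH_BIN_EDGES[k]),
        "proportional" if proportional else "equal",
    )
    assert out.total == pytest.approx(eff.total, rel=1e-9, abs=1e-9)
    assert (out.effort[reference.DEPTH_BIN_EDGES < reference.DEPTH_BIN_EDGES[k]] == 0).all()


class TestScenarioTable:
    def test_mean_year_reproduces_published_table(self, ref_table):
        landings = LandingsSeries(tons={"mean": MEAN_TONS})
        frame = scenario_table(landings, ref_table, [10, 20, 30, 40, 50])
        published_catch = [5252, 5157, 5252, 5363, 5996]
        published_birds = [4876, 2146, 1038, 310, 0]
        for row, catch, birds in zip(frame.itertuples(), published_catch, published_birds):
            assert row.catch_tons_mean == pytest.approx(catch, abs=2)
            assert row.birds_mean == pytest.approx(birds, abs=3)

    def test_two_year_mean_is_linear_in_tonnage(self, ref_table):
        t = 3000.0
        both = scenario_table(
            LandingsSeries(tons={"a": t, "b": 2 * t}), ref_table, [20]
        )
        mid = scenario_table(
            LandingsSeries(tons={"m": 1.5 * t}), ref_table, [20]
        )
        assert both["catch_tons_mean"][0] == pytest.approx(mid["catch_tons_mean"][0], rel=1e-9)
        assert both["birds_mean"][0] == pytest.approx(mid["birds_mean"][0], rel=1e-9)
        assert both["catch_tons_max"][0] == pytest.approx(2 * t / (1.5 * t) * mid["catch_tons_mean"][0], rel=1e-9)

    def test_max_year_scales_baseline_bycatch(self, unrounded):
        """The 7601 t maximum year scales the 6572-bird mean baseline to ≈9273."""
        eff = effort_from_landings(7601.0, unrounded)
        _, total = extrapolate_bycatch(eff, unrounded)
        assert total == pytest.approx(6572.0 * 7601.0 / MEAN_TONS, rel=1e-9)
        assert total == pytest.approx(9273, abs=2)

    def test_empty_landings_rejected(self, ref_table):
        with pytest.raises(DomainError):
            scenario_table(LandingsSeries(tons={}), ref_table, [10])


def test_landings_series_csv_roundtrip(tmp_path):
    series = LandingsSeries(tons={"2014": 5000.0, "2021": 7601.0})
    path = tmp_path / "landings.csv"
    series.to_csv(path)
    assert LandingsSeries.from_csv(path).tons == series.tons


def test_mammals_reported_relative_only(mean_year_effort, unrounded):
    res = simulate_restriction(mean_year_effort, unrounded, 30.0)
    assert not hasattr(res, "projected_mammal_bycatch")
    assert res.projected_mammal_relative == pytest.approx(1 + res.delta_mammals)
    assert res.delta_mammals > 0  # shifting effort deeper raises mammal exposure
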