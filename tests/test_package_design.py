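"""Frontier construction, threshold selection and league tables."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbpkit import (
    EconomyParams,
    Intervention,
    SynthSpec,
    budget_at_thresholds,
    frontier_table,
    generate,
    greedy_fill,
    metrics_at_level,
    rank_by_icer,
    rank_by_net_dalys,
    select_by_threshold,
)

from helpers import best_subset_exhaustive, net_of_subset


def iv(id, icer, cost, dalys, name=None, **kw):
    return Intervention(
        id=id,
        name=name or id.upper(),
        icer_usd_per_daly=icer,
        cost_full_usd=cost,
        dalys_full=dalys,
        **kw,
    )


class TestRankByIcer:
    def test_two_element_sort(self):
        a, b = iv("a", 29.0, 10.0, 1.0), iv("b", 22.0, 10.0, 1.0)
        assert [x.icer_usd_per_daly for x in rank_by_icer([a, b])] == [22.0, 29.0]

    def test_cost_saving_first_then_source_rank(self, malawi):
        ranked = rank_by_icer(malawi)
        assert ranked[0].name == "Cotrimoxazole for children"
        assert ranked[0].cost_saving
        assert ranked[1].name == "Mass media"
        # The full ordering reproduces the source league ranks 1..67.
        assert [x.icer_rank for x in ranked] == list(range(1, 68))

    def test_duplicate_icers_sorted_by_name(self):
        items = [iv(f"i{j}", 10.0, 1.0, 1.0, name=n) for j, n in enumerate("dacb")]
        expected = sorted(x.name for x in items)
        assert [x.name for x in rank_by_icer(items)] == expected


class TestSelectByThreshold:
    def test_malawi_package_scale(self, malawi, econ):
        pkg = select_by_threshold(malawi, econ, "A")
        assert len(pkg) == 48
        assert pkg.budget_usd == pytest.approx(265e6, rel=0.01)

    def test_membership_partitions_on_icer(self, malawi, econ):
        pkg = select_by_threshold(malawi, econ, "A")
        included = set(pkg.included_ids)
        for x in malawi:
            if x.cost_saving:
                assert x.id in included
            elif x.icer_usd_per_daly <= pkg.k_used:
                assert x.id in included
            else:
                assert x.id not in included

    def test_cumulative_cost_is_consistent(self, malawi, econ):
        pkg = select_by_threshold(malawi, econ, "A")
        assert list(pkg.cumulative_cost_usd) == sorted(pkg.cumulative_cost_usd)
        assert pkg.cumulative_cost_usd[-1] == pytest.approx(pkg.budget_usd)

    def test_threshold_below_all_icers_gives_empty_package(self):
        items = [iv("a", 100.0, 10.0, 1.0), iv("b", 200.0, 10.0, 1.0)]
        pkg = select_by_threshold(items, EconomyParams(k_usd_per_daly=1.0))
        assert len(pkg) == 0
        assert pkg.budget_usd == 0.0

    def test_empty_input_gives_empty_selection(self, plain_econ):
        pkg = select_by_threshold([], plain_econ)
        assert pkg.included_ids == ()
        assert pkg.budget_usd == 0.0


class TestFrontierTable:
    def test_single_intervention_cumulative_is_own_cost(self, plain_econ):
        t = frontier_table([iv("a", 10.0, 123.0, 5.0)])
        assert t["cumulative_cost_usd"].iloc[-1] == 123.0

    def test_last_cumulative_equals_total_cost(self):
        items = generate(SynthSpec(n_interventions=20, seed=7))
        t = frontier_table(items)
        assert t["cumulative_cost_usd"].iloc[-1] == pytest.approx(
            sum(x.cost_full_usd for x in items)
        )

    def test_cost_saving_rows_have_no_height(self):
        cs = Intervention(
            id="cs", name="CS", icer_usd_per_daly=None, cost_saving=True,
            cost_full_usd=-5.0, dalys_full=1.0,
        )
        t = frontier_table([cs, iv("a", 10.0, 1.0, 1.0)])
        assert math.isnan(t["dalys_per_1000_usd"].iloc[0])
        assert t["dalys_per_1000_usd"].iloc[1] == pytest.approx(100.0)


class TestNetDalyLeague:
    def test_malawi_top_two(self, malawi, econ):
        league = rank_by_net_dalys(malawi, econ, "full")
        assert league["name"].iloc[0] == "Male circumcision"
        # Ranked 30th by ICER but 2nd by net health: a large eligible
        # population outweighs a middling cost-effectiveness ratio.
        assert league["name"].iloc[1] == "Management of obstructed labour"
        assert league["icer_rank"].iloc[1] == 30

    def test_league_cumulative_cost_tracks_first_rows(self, malawi, econ):
        league = rank_by_net_dalys(malawi, econ, "full")
        assert league["cumulative_cost_usd"].iloc[1] == pytest.approx(147_830_000, abs=1e3)

    def test_identical_records_rank_in_name_order(self, plain_econ):
        items = [iv(f"i{j}", 10.0, 100.0, 50.0, name=n) for j, n in enumerate("cab")]
        league = rank_by_net_dalys(items, plain_econ)
        assert list(league["name"]) == ["a", "b", "c"]

    def test_actual_mode_uses_observed_levels(self, plain_econ):
        items = [iv("a", 10.0, 100.0, 50.0, implementation_level=0.5)]
        league = rank_by_net_dalys(items, plain_econ, "actual")
        assert league["total_dalys"].iloc[0] == pytest.approx(25.0)

    def test_unknown_level_mode_rejected(self, plain_econ):
        with pytest.raises(Exception):
            rank_by_net_dalys([iv("a", 10.0, 1.0, 1.0)], plain_econ, "half")


class TestBudgetAtThresholds:
    def test_scenario_a_budget(self, malawi, econ):
        budgets = budget_at_thresholds(malawi, econ)
        assert budgets["A"] == pytest.approx(265e6, rel=0.01)

    def test_lines_b_and_c_budgets(self, malawi, econ):
        # The GDP-per-capita norm scenarios: $362M and $380M packages.
        budgets = budget_at_thresholds(malawi, econ)
        assert budgets["B"] == pytest.approx(362e6, rel=0.01)
        assert budgets["C"] == pytest.approx(380e6, rel=0.01)

    def test_empty_scenarios_empty_mapping(self, malawi):
        assert budget_at_thresholds(malawi, EconomyParams(k_usd_per_daly=61.0)) == {}

    def test_threshold_above_all_icers_buys_everything(self):
        items = [iv("a", 10.0, 5.0, 1.0), iv("b", 20.0, 7.0, 1.0)]
        econ = EconomyParams(61.0, {"X": 21.0})
        assert budget_at_thresholds(items, econ)["X"] == pytest.approx(12.0)

    def test_budget_monotone_in_k(self, malawi):
        ks = [10.0, 61.0, 100.0, 372.0, 1116.0, 2000.0]
        econ = EconomyParams(61.0, {f"s{i}": k for i, k in enumerate(ks)})
        budgets = list(budget_at_thresholds(malawi, econ).values())
        assert budgets == sorted(budgets)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_threshold_package_matches_exhaustive_optimum(seed):
    """On small self-consistent sets the threshold rule is the net-DALY
    maximising subset found by enumerating all 2^n packages."""
    items = generate(SynthSpec(n_interventions=10, seed=seed, cost_saving_probability=0.2))
    econ = EconomyParams(k_usd_per_daly=61.0)
    pkg = select_by_threshold(items, econ)
    best_ids, best_net = best_subset_exhaustive(items, econ)
    assert set(pkg.included_ids) == best_ids
    assert pkg.total_net_dalys == pytest.approx(best_net, rel=1e-9, abs=1e-6)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_package_is_locally_optimal(seed):
    """Adding any excluded cost-positive intervention, or dropping any
    included one with ICER < k, strictly lowers total net health."""
    items = generate(SynthSpec(n_interventions=12, seed=seed))
    econ = EconomyParams(k_usd_per_daly=61.0)
    pkg = select_by_threshold(items, econ)
    included = set(pkg.included_ids)
    members = [x for x in items if x.id in included]
    for x in items:
        marginal = metrics_at_level(x, 1.0, econ).net_dalys
        if x.id not in included and not x.cost_saving:
            assert net_of_subset(members, econ) + marginal < net_of_subset(members, econ)
        if x.id in included and not x.cost_saving and x.icer_usd_per_daly < econ.k_usd_per_daly:
            reduced = [m for m in members if m.id != x.id]
            assert net_of_subset(reduced, econ) < net_of_subset(members, econ)


class TestGreedyFill:
    def test_non_binding_budget_recovers_threshold_package(self, malawi, econ):
        pkg = select_by_threshold(malawi, econ, "A")
        filled = greedy_fill(malawi, econ, pkg.budget_usd * 2)
        assert set(filled.included_ids) == set(pkg.included_ids)

    def test_respects_budget(self):
        items = [iv("a", 10.0, 60.0, 6.0), iv("b", 20.0, 60.0, 3.0), iv("c", 30.0, 60.0, 2.0)]
        econ = EconomyParams(k_usd_per_daly=61.0)
        filled = greedy_fill(items, econ, 120.0)
        assert set(filled.included_ids) == {"a", "b"}
        assert filled.budget_usd <= 120.0

    def test_skips_nonfitting_and_seats_cheaper(self):
        items = [iv("big", 10.0, 100.0, 10.0), iv("small", 20.0, 30.0, 1.5)]
        filled = greedy_fill(items, EconomyParams(k_usd_per_daly=61.0), 50.0)
        assert set(filled.included_ids) == {"small"}

    def test_forced_in_beyond_budget_raises(self):
        items = [iv("a", 10.0, 100.0, 10.0)]
        with pytest.raises(Exception):
            greedy_fill(items, EconomyParams(k_usd_per_daly=61.0), 50.0, forced_in=["a"])
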