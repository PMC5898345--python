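"""Cost-effectiveness frontier, threshold selection and net-DALY league tables.

A health benefits package is selected by comparing each intervention's ICER
with the health opportunity cost k: at full implementation, including a
cost-positive intervention with ICER < k raises total net DALYs and including
one with ICER > k lowers it, so the unconstrained health-maximising package
is exactly {cost-saving} + {ICER <= k} and its budget is an *output* of the
threshold, not an input. A budget-capped greedy variant is provided for
analyses where the budget is fixed (donor conditionality, expansion).
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import pandas as pd

from .core_metrics import DomainError, EconomyParams, Intervention, metrics_at_level

__all__ = [
    "PackageSelection",
    "rank_by_icer",
    "select_by_threshold",
    "frontier_table",
    "rank_by_net_dalys",
    "budget_at_thresholds",
    "greedy_fill",
]


@dataclass(frozen=True)
class PackageSelection:
    """An ordered set of included interventions with cumulative cost totals.

    ``included_ids`` is ordered by ascending ICER (cost-saving first) and
    ``cumulative_cost_usd`` aligns with it; the last cumulative entry equals
    ``budget_usd``, the package cost at full implementation.
    """

    threshold_label: str
    k_used: float
    included_ids: tuple[str, ...]
    cumulative_cost_usd: tuple[float, ...]
    budget_usd: float
    total_dalys: float
    total_net_dalys: float

    def __len__(self) -> int:
        return len(self.included_ids)

    def members(self, interventions: Iterable[Intervention]) -> list[Intervention]:
        """Resolve included ids back to intervention records, in package order."""
        by_id = {iv.id: iv for iv in interventions}
        return [by_id[i] for i in self.included_ids]


def _icer_sort_key(iv: Intervention) -> tuple:
    # Cost-saving sorts before any ICER; explicit source ranks (which encode
    # the unrounded ICER order) break ties among equal rounded ICERs.
    return (
        0 if iv.cost_saving else 1,
        0.0 if iv.cost_saving else iv.icer_usd_per_daly,
        iv.icer_rank if iv.icer_rank is not None else math.inf,
        iv.name,
        iv.id,
    )


def rank_by_icer(interventions: Sequence[Intervention]) -> list[Intervention]:
    """Order interventions from most to least cost-effective.

    Cost-saving interventions come first, then ascending ICER; ties among
    equal ICERs break by the source's own rank when present, then by name,
    then id, so the ordering is deterministic.
    """
    return sorted(interventions, key=_icer_sort_key)


def _build_selection(
    members: Sequence[Intervention], econ: EconomyParams, k: float, label: str
) -> PackageSelection:
    econ_k = EconomyParams(k_usd_per_daly=k)
    cumulative: list[float] = []
    running = 0.0
    total_dalys = 0.0
    total_net = 0.0
    for iv in members:
        running += iv.cost_full_usd
        cumulative.append(running)
        m = metrics_at_level(iv, 1.0, econ_k)
        total_dalys += m.total_dalys
        total_net += m.net_dalys
    return PackageSelection(
        threshold_label=label,
        k_used=k,
        included_ids=tuple(iv.id for iv in members),
        cumulative_cost_usd=tuple(cumulative),
        budget_usd=running,
        total_dalys=total_dalys,
        total_net_dalys=total_net,
    )


def select_by_threshold(
    interventions: Sequence[Intervention],
    econ: EconomyParams,
    label: str | None = None,
) -> PackageSelection:
    """Select the unconstrained health-maximising package at a threshold.

    Includes every cost-saving intervention plus every intervention with
    ICER <= k, where k is ``econ.k_usd_per_daly`` or, if ``label`` is given,
    the corresponding scenario value. The budget is the total cost of the
    selected interventions at full implementation.
    """
    k = econ.k_for(label)
    members = [
        iv
        for iv in rank_by_icer(interventions)
        if iv.cost_saving or iv.icer_usd_per_daly <= k
    ]
    return _build_selection(members, econ, k, label if label is not None else "default")


def frontier_table(interventions: Sequence[Intervention]) -> pd.DataFrame:
    """Tabulate the cost-effectiveness frontier behind the budget-line plot.

    One row per intervention in ascending-ICER order with the bar geometry:
    height (DALYs averted per $1000) and width (total cost), plus the
    cumulative cost at which each bar ends. Cost-saving rows have no defined
    height and carry NaN there.
    """
    rows = []
    running = 0.0
    for rank, iv in enumerate(rank_by_icer(interventions), start=1):
        running += iv.cost_full_usd
        rows.append(
            {
                "rank": rank,
                "id": iv.id,
                "name": iv.name,
                "icer_usd_per_daly": math.nan if iv.cost_saving else iv.icer_usd_per_daly,
                "cost_saving": iv.cost_saving,
                "dalys_per_1000_usd": math.nan
                if iv.cost_saving
                else 1000.0 / iv.icer_usd_per_daly,
                "cost_full_usd": iv.cost_full_usd,
                "cumulative_cost_usd": running,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rank",
            "id",
            "name",
            "icer_usd_per_daly",
            "cost_saving",
            "dalys_per_1000_usd",
            "cost_full_usd",
            "cumulative_cost_usd",
        ],
    )


def rank_by_net_dalys(
    interventions: Sequence[Intervention],
    econ: EconomyParams,
    level_mode: str = "full",
) -> pd.DataFrame:
    """League table of interventions ranked by net DALYs averted (descending).

    ``level_mode`` selects the implementation level at which value is
    evaluated: ``"full"`` (100%) or ``"actual"`` (each intervention's observed
    level). Ties break by name. The cumulative-cost column runs down the
    league order, mirroring the source table convention.
    """
    if level_mode not in ("full", "actual"):
        raise DomainError(f"level_mode must be 'full' or 'actual', got {level_mode!r}")
    rows = []
    for iv in interventions:
        level = 1.0 if level_mode == "full" else iv.implementation_level
        m = metrics_at_level(iv, level, econ)
        rows.append(
            {
                "id": iv.id,
                "name": iv.name,
                "icer_rank": iv.icer_rank,
                "icer_usd_per_daly": math.nan if iv.cost_saving else iv.icer_usd_per_daly,
                "cost_saving": iv.cost_saving,
                "cases_per_year": iv.cases_per_year,
                "implementation": m.implementation,
                "total_cost_usd": m.total_cost_usd,
                "total_dalys": m.total_dalys,
                "net_dalys": m.net_dalys,
                "financial_value_usd": m.financial_value_usd,
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["net_dalys", "name"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table.insert(0, "rank", range(1, len(table) + 1))
    table["cumulative_cost_usd"] = table["total_cost_usd"].cumsum()
    return table


def budget_at_thresholds(
    interventions: Sequence[Intervention], econ: EconomyParams
) -> dict[str, float]:
    """Full-implementation package budget implied by each threshold scenario."""
    return {
        label: select_by_threshold(interventions, econ, label).budget_usd
        for label in econ.threshold_scenarios
    }


def greedy_fill(
    interventions: Sequence[Intervention],
    econ: EconomyParams,
    budget_usd: float,
    forced_in: Iterable[str] = (),
    forced_out: Iterable[str] = (),
    label: str = "budget-capped",
) -> PackageSelection:
    """Fill a fixed budget greedily in ascending-ICER order, whole interventions.

    Forced-in interventions are seated first (whatever their ICER); remaining
    budget is then filled from the non-excluded candidates that offer positive
    net health (cost-saving or ICER <= k), most cost-effective first, skipping
    any whose whole cost no longer fits. Cost-saving interventions release
    budget when their cost is negative. The result is a lower bound on the
    budget-constrained optimum; with a non-binding budget it coincides with
    the threshold package.

    Raises
    ------
    DomainError
        If the forced-in set alone costs more than the budget.
    """
    k = econ.k_usd_per_daly
    forced_in = set(forced_in)
    forced_out = set(forced_out)
    if forced_in & forced_out:
        raise DomainError("forced_in and forced_out must be disjoint")
    by_id = {iv.id: iv for iv in interventions}
    missing = (forced_in | forced_out) - set(by_id)
    if missing:
        raise KeyError(f"unknown intervention ids: {sorted(missing)}")

    ranked = rank_by_icer(interventions)
    members: list[Intervention] = []
    spent = 0.0
    for iv in ranked:
        if iv.id in forced_in:
            members.append(iv)
            spent += iv.cost_full_usd
    if spent > budget_usd and not math.isclose(spent, budget_usd, rel_tol=1e-12):
        raise DomainError(
            f"forced-in interventions cost {spent:.2f} USD, exceeding the "
            f"budget of {budget_usd:.2f} USD"
        )
    for iv in ranked:
        if iv.id in forced_in or iv.id in forced_out:
            continue
        if not (iv.cost_saving or iv.icer_usd_per_daly <= k):
            continue
        if spent + iv.cost_full_usd <= budget_usd or iv.cost_full_usd <= 0:
            members.append(iv)
            spent += iv.cost_full_usd
    members.sort(key=_icer_sort_key)
    return _build_selection(members, econ, k, label)
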