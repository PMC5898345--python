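"""Health opportunity cost of donor conditionalities and non-health objectives.

Donors often attach conditions to assistance: particular interventions must
(or must not) be funded, extra resources are earmarked, or funding is offered
only as a match. Forcing a not-cost-effective intervention into a package
always reduces the total health the package generates; the difference in net
DALYs between the unconstrained health-maximising package and the best
package satisfying the conditions is the *minimum* health opportunity cost of
those conditions. Objectives beyond health (equity, continuum of care,
complementarities) are quantified the same way, by forcing the corresponding
interventions in or out and measuring the forgone net health.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field, replace

from .core_metrics import DomainError, EconomyParams, Intervention
from .package_design import PackageSelection, greedy_fill

__all__ = [
    "InfeasibleScenarioError",
    "MatchedOffer",
    "DonorScenario",
    "MatchedFundingDecision",
    "ConditionalityCost",
    "constrained_package",
    "conditionality_cost",
    "evaluate_matched_funding",
]


class InfeasibleScenarioError(DomainError):
    """The forced-in interventions alone cost more than the available budget."""


@dataclass(frozen=True)
class MatchedOffer:
    """A donor offer to pay ``donor_share`` of one intervention's cost."""

    intervention_id: str
    donor_share: float

    def __post_init__(self) -> None:
        if not 0.0 < self.donor_share <= 1.0:
            raise DomainError("donor_share must lie in (0, 1]")


@dataclass(frozen=True)
class DonorScenario:
    """A set of conditions attached to donor assistance.

    ``forced_in_ids`` must be included as a condition of the resources;
    ``forced_out_ids`` may not be funded; ``budget_delta_usd`` is any
    earmarked addition to the budget that comes with the conditions (0 for a
    pure restriction); ``matched`` optionally records a matched-funding offer.
    """

    forced_in_ids: frozenset[str] = field(default_factory=frozenset)
    forced_out_ids: frozenset[str] = field(default_factory=frozenset)
    budget_delta_usd: float = 0.0
    matched: MatchedOffer | None = None

    def __post_init__(self) -> None:
        fin = frozenset(self.forced_in_ids)
        fout = frozenset(self.forced_out_ids)
        object.__setattr__(self, "forced_in_ids", fin)
        object.__setattr__(self, "forced_out_ids", fout)
        if fin & fout:
            raise DomainError("forced_in_ids and forced_out_ids must be disjoint")


@dataclass(frozen=True)
class ConditionalityCost:
    """Net-health comparison of unconstrained vs condition-respecting packages."""

    net_dalys_unconstrained: float
    net_dalys_constrained: float
    health_cost_dalys: float
    financial_cost_usd: float
    unconstrained: PackageSelection
    constrained: PackageSelection


@dataclass(frozen=True)
class MatchedFundingDecision:
    """System-side value of a matched-funding offer and the resulting advice."""

    intervention_id: str
    donor_share: float
    system_cost_usd: float
    net_dalys_to_system: float
    recommend: str  # "accept" | "reject"


def constrained_package(
    all_interventions: Sequence[Intervention],
    econ: EconomyParams,
    scenario: DonorScenario,
    budget_usd: float,
) -> PackageSelection:
    """Best greedy package under a budget and a donor scenario's conditions.

    Forced-in interventions are seated first; the remaining budget (including
    any earmarked ``budget_delta_usd``) is filled in ascending-ICER order from
    the candidates not forced out.

    Raises
    ------
    InfeasibleScenarioError
        If the forced-in set alone exceeds the budget.
    """
    try:
        return greedy_fill(
            all_interventions,
            econ,
            budget_usd + scenario.budget_delta_usd,
            forced_in=scenario.forced_in_ids,
            forced_out=scenario.forced_out_ids,
            label="constrained",
        )
    except DomainError as err:
        if "forced-in" in str(err):
            raise InfeasibleScenarioError(str(err)) from err
        raise


def conditionality_cost(
    all_interventions: Sequence[Intervention],
    econ: EconomyParams,
    scenario: DonorScenario,
    budget_usd: float,
) -> ConditionalityCost:
    """Minimum health opportunity cost of a donor scenario's restrictions.

    The comparator is the unconstrained health-maximising package with the
    *same total resources* (budget plus any earmarked delta), so the cost
    measured is that of the restrictions alone, never of the resources; it is
    therefore non-negative, and zero for vacuous conditions. The financial
    cost converts the forgone net health to money at k.

    Both packages come from the greedy fill, a lower bound on the knapsack
    optimum. A constrained fill can occasionally pack the budget better than
    the unconstrained one; since any package satisfying the conditions is
    also feasible without them, the comparator then adopts that selection,
    keeping the reported cost a non-negative lower bound on the true
    opportunity cost (hence "minimum").
    """
    unconstrained = greedy_fill(
        all_interventions,
        econ,
        budget_usd + scenario.budget_delta_usd,
        label="unconstrained",
    )
    constrained = constrained_package(all_interventions, econ, scenario, budget_usd)
    if constrained.total_net_dalys > unconstrained.total_net_dalys:
        unconstrained = replace(constrained, threshold_label="unconstrained")
    health_cost = unconstrained.total_net_dalys - constrained.total_net_dalys
    return ConditionalityCost(
        net_dalys_unconstrained=unconstrained.total_net_dalys,
        net_dalys_constrained=constrained.total_net_dalys,
        health_cost_dalys=health_cost,
        financial_cost_usd=health_cost * econ.k_usd_per_daly,
        unconstrained=unconstrained,
        constrained=constrained,
    )


def evaluate_matched_funding(
    iv: Intervention, donor_share: float, econ: EconomyParams
) -> MatchedFundingDecision:
    """Accept-or-reject advice on a matched-funding offer.

    The system bears ``(1 - donor_share)`` of the intervention's cost, so its
    net health from acceptance is ``dalys_full - (1 - share) * cost_full / k``.
    The offer is worth accepting only when that net is strictly positive:
    matched money for an intervention without net health benefit still
    displaces more health elsewhere than the intervention delivers.
    """
    if not 0.0 < donor_share <= 1.0:
        raise DomainError("donor_share must lie in (0, 1]")
    system_cost = (1.0 - donor_share) * iv.cost_full_usd
    net = iv.dalys_full - system_cost / econ.k_usd_per_daly
    return MatchedFundingDecision(
        intervention_id=iv.id,
        donor_share=donor_share,
        system_cost_usd=system_cost,
        net_dalys_to_system=net,
        recommend="accept" if net > 0 else "reject",
    )
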