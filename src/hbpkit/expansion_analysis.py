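"""Spending the implementation gap on extra interventions vs on scale-up.

A ministry facing binding implementation constraints can accept them and use
the resulting spending gap to fund interventions beyond the threshold
(ICER > k). The health case for that depends on the DALYs those additions
avert *at their observed implementation levels*, compared against the DALYs
that the same money might unlock by relaxing the constraints on the package
already included. Because every addition has ICER > k, expansion always
lowers total net DALYs relative to the threshold package; the comparison
here is in gross DALYs, as a best case for expansion.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

from .core_metrics import DomainError, EconomyParams, Intervention
from .implementation_analysis import spending_gap, strengthening_potential
from .package_design import PackageSelection, rank_by_icer

__all__ = ["ExpansionReport", "expand_with_gap", "breakeven_fraction"]


@dataclass(frozen=True)
class ExpansionReport:
    """Outcome of funding beyond-threshold interventions from the spending gap."""

    added_ids: tuple[str, ...]
    gap_usd: float
    gap_spent_usd: float
    added_dalys: float
    total_dalys_with_expansion: float
    forgone_vs_implementation_dalys: float
    breakeven_fraction: float


def breakeven_fraction(added_dalys: float, strengthening_potential_dalys: float) -> float:
    """Fraction of the strengthening potential that expansion would deliver.

    If implementation efforts funded by the gap achieved more than this
    fraction of their potential, they would beat package expansion.

    Raises
    ------
    DomainError
        If the strengthening potential is not strictly positive.
    """
    if strengthening_potential_dalys <= 0:
        raise DomainError(
            "break-even fraction undefined for non-positive strengthening potential"
        )
    return added_dalys / strengthening_potential_dalys


def expand_with_gap(
    all_interventions: Sequence[Intervention],
    package: PackageSelection,
    econ: EconomyParams,
    use_actual_levels: bool = True,
) -> ExpansionReport:
    """Fund excluded interventions from the package's spending gap.

    Candidates are the interventions outside ``package`` (those with
    ICER > k), taken in ascending-ICER order at their actual-implementation
    cost, added while the cumulative cost fits within the gap (whole
    interventions; non-fitting candidates are skipped and cheaper ones
    further down the list may still be seated). ``use_actual_levels=False``
    evaluates additions at full implementation instead, as a sensitivity.
    """
    members = package.members(all_interventions)
    gap = spending_gap(members, econ)
    pot = strengthening_potential(members, econ)

    included = set(package.included_ids)
    candidates = [iv for iv in rank_by_icer(all_interventions) if iv.id not in included]

    added: list[str] = []
    spent = 0.0
    added_dalys = 0.0
    for iv in candidates:
        level = iv.implementation_level if use_actual_levels else 1.0
        cost = iv.cost_full_usd * level
        if spent + cost <= gap or cost <= 0:
            added.append(iv.id)
            spent += cost
            added_dalys += iv.dalys_full * level

    total_with_expansion = pot.dalys_actual + added_dalys
    return ExpansionReport(
        added_ids=tuple(added),
        gap_usd=gap,
        gap_spent_usd=spent,
        added_dalys=added_dalys,
        total_dalys_with_expansion=total_with_expansion,
        forgone_vs_implementation_dalys=pot.dalys_full - total_with_expansion,
        breakeven_fraction=(
            breakeven_fraction(added_dalys, pot.potential) if pot.potential > 0 else 0.0
        ),
    )
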