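"""Value of scaling interventions up from actual to full implementation.

Observed coverage in low-income systems is often far below 100%; the value
of removing the demand- and supply-side constraints that cause this is the
difference between an intervention's metrics at full and at actual
implementation. The financial-value delta doubles as a budget ceiling: it is
the most that could be spent relaxing the constraints for the scale-up to
remain a cost-effective use of resources. Aggregated over a package, the
cost delta is the *spending gap* and the DALY delta is the maximum health
gain that system strengthening could achieve.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

import pandas as pd

from .core_metrics import (
    EconomyParams,
    Intervention,
    ValueMetrics,
    delta_metrics,
    metrics_at_level,
)

__all__ = [
    "ScaleUpRecord",
    "ScaleUpReport",
    "StrengtheningPotential",
    "scaleup_value",
    "rank_by_scaleup_value",
    "spending_gap",
    "strengthening_potential",
    "scaleup_report",
]


@dataclass(frozen=True)
class ScaleUpRecord:
    """Full, actual and delta metrics for one intervention."""

    id: str
    name: str
    metrics_full: ValueMetrics
    metrics_actual: ValueMetrics
    delta: ValueMetrics


@dataclass(frozen=True)
class StrengtheningPotential:
    """Aggregate DALYs at full and actual implementation and their difference."""

    dalys_full: float
    dalys_actual: float
    potential: float


@dataclass(frozen=True)
class ScaleUpReport:
    """Per-intervention scale-up records plus package-level aggregates."""

    per_intervention: tuple[ScaleUpRecord, ...]
    spending_gap_usd: float
    total_dalys_full: float
    total_dalys_actual: float
    strengthening_potential_dalys: float


def scaleup_value(iv: Intervention, econ: EconomyParams) -> ScaleUpRecord:
    """Metrics of moving one intervention from its actual level to 100%.

    Every delta field is exactly full minus actual; at an actual level of 1
    all deltas are zero, and at 0 the delta equals the full metrics.
    """
    full = metrics_at_level(iv, 1.0, econ)
    actual = metrics_at_level(iv, iv.implementation_level, econ)
    return ScaleUpRecord(
        id=iv.id,
        name=iv.name,
        metrics_full=full,
        metrics_actual=actual,
        delta=delta_metrics(full, actual),
    )


def rank_by_scaleup_value(
    interventions: Sequence[Intervention], econ: EconomyParams
) -> pd.DataFrame:
    """League table ranked by the financial value of full implementation.

    Descending scale-up financial value, ties broken by name: positive-value
    rows first, already-fully-implemented rows (delta zero) in the middle and
    negative-value rows (scaling up destroys net health) last. The financial
    value column is also the ceiling on what could cost-effectively be spent
    removing each intervention's implementation constraints.
    """
    rows = []
    for iv in interventions:
        rec = scaleup_value(iv, econ)
        rows.append(
            {
                "id": iv.id,
                "name": iv.name,
                "icer_rank": iv.icer_rank,
                "icer_usd_per_daly": math.nan if iv.cost_saving else iv.icer_usd_per_daly,
                "implementation_level": iv.implementation_level,
                "cost_full_usd": rec.metrics_full.total_cost_usd,
                "cost_actual_usd": rec.metrics_actual.total_cost_usd,
                "dalys_full": rec.metrics_full.total_dalys,
                "dalys_actual": rec.metrics_actual.total_dalys,
                "net_dalys_full": rec.metrics_full.net_dalys,
                "net_dalys_actual": rec.metrics_actual.net_dalys,
                "scaleup_dalys": rec.delta.total_dalys,
                "scaleup_cost_usd": rec.delta.total_cost_usd,
                "scaleup_net_dalys": rec.delta.net_dalys,
                "scaleup_financial_value_usd": rec.delta.financial_value_usd,
                "max_spend_on_constraints_usd": rec.delta.financial_value_usd,
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["scaleup_financial_value_usd", "name"],
        ascending=[False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table.insert(0, "rank", range(1, len(table) + 1))
    return table


def spending_gap(members: Sequence[Intervention], econ: EconomyParams) -> float:
    """Package full-implementation cost minus actual spend, in USD.

    Non-negative whenever all implementation levels are <= 1.
    """
    return sum(
        iv.cost_full_usd - iv.cost_full_usd * iv.implementation_level
        for iv in members
    )


def strengthening_potential(
    members: Sequence[Intervention], econ: EconomyParams
) -> StrengtheningPotential:
    """Aggregate DALYs averted at full vs actual implementation over a package."""
    full = sum(iv.dalys_full for iv in members)
    actual = sum(iv.dalys_full * iv.implementation_level for iv in members)
    return StrengtheningPotential(
        dalys_full=full, dalys_actual=actual, potential=full - actual
    )


def scaleup_report(
    members: Sequence[Intervention], econ: EconomyParams
) -> ScaleUpReport:
    """Full scale-up report over a package: per-intervention deltas + aggregates."""
    records = tuple(scaleup_value(iv, econ) for iv in members)
    pot = strengthening_potential(members, econ)
    return ScaleUpReport(
        per_intervention=records,
        spending_gap_usd=spending_gap(members, econ),
        total_dalys_full=pot.dalys_full,
        total_dalys_actual=pot.dalys_actual,
        strengthening_potential_dalys=pot.potential,
    )
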