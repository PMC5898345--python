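"""Domain types and per-intervention metrics of value.

The central quantity is the *net DALYs averted* by an intervention: the
DALYs it averts minus the DALYs the same money could have averted elsewhere
in the healthcare system. The conversion between money and forgone health is
the health opportunity cost parameter ``k`` (USD per DALY averted at the
margin of the system's budget; $61 for Malawi). The *financial value to the
healthcare system* re-expresses net DALYs in money at ``k``: the extra
budget that would be needed to produce the same net health with other
interventions.

All currency is raw USD and all health totals are raw DALYs; loaders convert
tables printed in thousands before anything here sees them.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field, replace

__all__ = [
    "DomainError",
    "UndefinedRatioError",
    "Intervention",
    "EconomyParams",
    "ValueMetrics",
    "dalys_per_1000_usd",
    "metrics_at_level",
    "scale_metrics",
    "delta_metrics",
]


class DomainError(ValueError):
    """An argument is outside the domain of a metric (e.g. a negative ICER)."""


class UndefinedRatioError(DomainError):
    """The requested ratio is undefined for a cost-saving intervention.

    A cost-saving intervention has no meaningful cost-per-DALY ratio; callers
    that tabulate DALYs-per-$1000 must branch on :attr:`Intervention.cost_saving`.
    """


@dataclass(frozen=True)
class Intervention:
    """One candidate service for a health benefits package.

    Parameters
    ----------
    id : str
        Short stable identifier.
    name : str
        Display name.
    icer_usd_per_daly : float or None
        Incremental cost-effectiveness ratio in USD per DALY averted.
        ``None`` is only valid when ``cost_saving`` is set.
    cost_saving : bool
        Marks an intervention that saves resources overall. Cost-saving
        interventions have no defined ICER, sort before every cost-positive
        intervention and are always included in a package.
    cases_per_year : float
        Size of the eligible patient population (persons per year).
    cost_full_usd : float
        Total annual cost at full implementation (cost per case x cases).
        May be negative (or, in imperfect source data, non-negative) when
        ``cost_saving`` is set.
    dalys_full : float
        Total DALYs averted per year at full implementation.
    implementation_level : float
        Fraction of the eligible population actually reached, in [0, 1].
    flags : frozenset of str
        Policy labels (e.g. ``donor-required``, ``equity``).
    icer_rank : int or None
        Optional rank from the source league table. Printed ICERs are often
        rounded; when the source also prints its own cost-effectiveness rank,
        that rank preserves the unrounded order and is used to break ties
        among equal (rounded) ICERs.
    low_confidence : bool
        Marks rows whose numeric fields are uncertain transcriptions.
    """

    id: str
    name: str
    icer_usd_per_daly: float | None
    cost_saving: bool = False
    cases_per_year: float = 0.0
    cost_full_usd: float = 0.0
    dalys_full: float = 0.0
    implementation_level: float = 1.0
    flags: frozenset[str] = field(default_factory=frozenset)
    icer_rank: int | None = None
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.implementation_level <= 1.0:
            raise DomainError(
                f"{self.id}: implementation_level {self.implementation_level!r} "
                "must lie in [0, 1]"
            )
        if self.cases_per_year < 0:
            raise DomainError(f"{self.id}: cases_per_year must be >= 0")
        if self.cost_saving:
            if self.icer_usd_per_daly is not None:
                raise DomainError(
                    f"{self.id}: a cost-saving intervention has no defined ICER"
                )
        else:
            if self.icer_usd_per_daly is None:
                raise DomainError(f"{self.id}: icer_usd_per_daly is required")
            if self.icer_usd_per_daly <= 0:
                raise DomainError(f"{self.id}: icer_usd_per_daly must be > 0")
            if self.cost_full_usd < 0:
                raise DomainError(
                    f"{self.id}: negative cost requires the cost_saving marker"
                )
        if not isinstance(self.flags, frozenset):
            object.__setattr__(self, "flags", frozenset(self.flags))


@dataclass(frozen=True)
class EconomyParams:
    """Health opportunity cost of the system and alternative threshold scenarios.

    ``k_usd_per_daly`` is the marginal productivity of healthcare spending
    expressed as USD per DALY averted: spending one more dollar elsewhere in
    the system averts ``1/k`` DALYs. ``threshold_scenarios`` maps labels to
    alternative values of k (e.g. ``{"A": 61, "B": 372, "C": 1116}``),
    strictly increasing in the given order.
    """

    k_usd_per_daly: float = 61.0
    threshold_scenarios: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k_usd_per_daly <= 0:
            raise DomainError("k_usd_per_daly must be > 0")
        values = list(self.threshold_scenarios.values())
        if any(v <= 0 for v in values):
            raise DomainError("threshold scenario values must be > 0")
        if any(b <= a for a, b in zip(values, values[1:])):
            raise DomainError("threshold scenario values must be strictly increasing")

    def k_for(self, label: str | None) -> float:
        """Resolve a scenario label to its k value; ``None`` means the default k."""
        if label is None:
            return self.k_usd_per_daly
        try:
            return float(self.threshold_scenarios[label])
        except KeyError:
            raise KeyError(
                f"unknown threshold scenario {label!r}; "
                f"known: {list(self.threshold_scenarios)}"
            ) from None


@dataclass(frozen=True)
class ValueMetrics:
    """Computed value of one intervention at a given implementation level.

    ``net_dalys = total_dalys - total_cost_usd / k`` and
    ``financial_value_usd = net_dalys * k``. A negative total cost (resource
    savings) therefore *adds* health: the savings fund other interventions.
    """

    intervention_id: str
    implementation: float
    total_cost_usd: float
    total_dalys: float
    net_dalys: float
    financial_value_usd: float
    k_usd_per_daly: float


def dalys_per_1000_usd(icer: float | None) -> float:
    """DALYs averted per $1000 spent, the reciprocal-scale view of an ICER.

    Raises
    ------
    UndefinedRatioError
        If ``icer`` is ``None`` (cost-saving marker).
    DomainError
        If ``icer`` is not strictly positive.
    """
    if icer is None:
        raise UndefinedRatioError("ratio undefined for a cost-saving intervention")
    if icer <= 0 or math.isnan(icer):
        raise DomainError(f"icer must be > 0, got {icer!r}")
    return 1000.0 / icer


def metrics_at_level(
    iv: Intervention, level: float, econ: EconomyParams
) -> ValueMetrics:
    """Evaluate an intervention's value at implementation fraction ``level``.

    Cost and DALYs scale linearly with coverage (constant returns); net DALYs
    and financial value follow from the scaled components.
    """
    if not 0.0 <= level <= 1.0:
        raise DomainError(f"implementation level {level!r} must lie in [0, 1]")
    k = econ.k_usd_per_daly
    total_cost = iv.cost_full_usd * level
    total_dalys = iv.dalys_full * level
    net = total_dalys - total_cost / k
    return ValueMetrics(
        intervention_id=iv.id,
        implementation=level,
        total_cost_usd=total_cost,
        total_dalys=total_dalys,
        net_dalys=net,
        financial_value_usd=net * k,
        k_usd_per_daly=k,
    )


def scale_metrics(full: ValueMetrics, level: float) -> ValueMetrics:
    """Scale full-implementation metrics down to a partial coverage level.

    Cost and DALYs are multiplied by ``level``; net DALYs and financial value
    are recomputed from the scaled components (identical to direct scaling
    under linearity, which the test suite asserts as a property).
    """
    if not 0.0 <= level <= 1.0:
        raise DomainError(f"implementation level {level!r} must lie in [0, 1]")
    k = full.k_usd_per_daly
    total_cost = full.total_cost_usd * level
    total_dalys = full.total_dalys * level
    net = total_dalys - total_cost / k
    return replace(
        full,
        implementation=full.implementation * level,
        total_cost_usd=total_cost,
        total_dalys=total_dalys,
        net_dalys=net,
        financial_value_usd=net * k,
    )


def delta_metrics(full: ValueMetrics, actual: ValueMetrics) -> ValueMetrics:
    """Component-wise difference ``full - actual`` between two evaluations.

    This is the value of moving from the actual to the full level: every
    cost/health field is differenced exactly, so printed source components can
    be differenced without reference to k.
    """
    if full.intervention_id != actual.intervention_id:
        raise DomainError(
            "delta requires metrics for the same intervention, got "
            f"{full.intervention_id!r} vs {actual.intervention_id!r}"
        )
    return ValueMetrics(
        intervention_id=full.intervention_id,
        implementation=full.implementation - actual.implementation,
        total_cost_usd=full.total_cost_usd - actual.total_cost_usd,
        total_dalys=full.total_dalys - actual.total_dalys,
        net_dalys=full.net_dalys - actual.net_dalys,
        financial_value_usd=full.financial_value_usd - actual.financial_value_usd,
        k_usd_per_daly=full.k_usd_per_daly,
    )
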