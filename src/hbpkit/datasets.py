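"""Packaged Malawi league-table fixture and a synthetic intervention generator.

The fixture transcribes the published Malawi essential-health-package league
tables (67 unique interventions; ICERs from cost-saving to $1646 per DALY
averted, eligible populations from a few hundred to ~17 million cases per
year, 2014 implementation levels from 0% to 100%). Where the source gives
one intervention at two precisions, the higher precision wins. A companion
record of the source's printed aggregates (package budget, spending gap,
DALY totals and the schistosomiasis scale-up worked example) ships alongside
for cross-checks; the printed net-DALY columns embed an internal cost basis
that is not recoverable from the printed inputs, so those columns are
carried as reference values only and are never recomputed here.

The synthetic generator emulates the fixture's empirical shape: log-uniform
ICERs straddling the threshold, log-uniform eligible populations and
Beta-distributed implementation levels. Records are self-consistent by
construction (cost = ICER x DALYs), which real league tables are not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Any

import numpy as np

from .core_metrics import DomainError, EconomyParams, Intervention
from .io import load_interventions

__all__ = [
    "SynthSpec",
    "generate",
    "malawi_fixture",
    "malawi_reference",
    "default_economy",
]

_FIXTURE_CSV = "data/malawi_interventions.csv"
_REFERENCE_JSON = "data/malawi_reference.json"


def default_economy() -> EconomyParams:
    """Malawi opportunity-cost parameter and the three threshold scenarios.

    k = $61 per DALY averted (empirical marginal productivity of the
    healthcare system); scenarios B and C are the 1x and 3x GDP-per-capita
    norms ($372 and $1116).
    """
    return EconomyParams(
        k_usd_per_daly=61.0,
        threshold_scenarios={"A": 61.0, "B": 372.0, "C": 1116.0},
    )


def malawi_fixture() -> list[Intervention]:
    """The 67-intervention Malawi league-table transcription."""
    with resources.as_file(
        resources.files("hbpkit").joinpath(_FIXTURE_CSV)
    ) as path:
        return load_interventions(path)


def malawi_reference() -> dict[str, Any]:
    """Printed aggregate values from the source tables, for cross-checks.

    Keys: ``package`` (size, budget, DALY totals, spending gap),
    ``expansion`` (added/total/forgone DALYs) and ``schistosomiasis`` (the
    full/actual/delta rows of the scale-up worked example). All currency in
    USD, all health in DALYs.
    """
    text = resources.files("hbpkit").joinpath(_REFERENCE_JSON).read_text()
    return json.loads(text)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic intervention-set generator.

    ICERs and case counts are log-uniform (both span orders of magnitude in
    real league tables); DALYs averted per case are log-uniform over a range
    covering preventive interventions (small per-case effect, huge
    populations) through curative ones; implementation levels are
    Beta(2, 2), matching an observed mid-range mean with full 0-1 spread.
    """

    n_interventions: int = 50
    icer_range: tuple[float, float] = (1.0, 2000.0)
    cases_range: tuple[float, float] = (500.0, 2.0e7)
    dalys_per_case_range: tuple[float, float] = (1e-3, 10.0)
    implementation_beta: tuple[float, float] = (2.0, 2.0)
    cost_saving_probability: float = 0.05
    savings_per_daly_range: tuple[float, float] = (1.0, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_interventions < 0:
            raise DomainError("n_interventions must be >= 0")
        for name in ("icer_range", "cases_range", "dalys_per_case_range",
                     "savings_per_daly_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise DomainError(f"{name} bounds must be positive and ordered")
        if not 0.0 <= self.cost_saving_probability <= 1.0:
            raise DomainError("cost_saving_probability must lie in [0, 1]")
        if any(p <= 0 for p in self.implementation_beta):
            raise DomainError("implementation_beta parameters must be > 0")
        if self.seed < 0:
            raise DomainError("seed must be a non-negative integer")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))


def generate(spec: SynthSpec) -> list[Intervention]:
    """Draw a self-consistent synthetic intervention set.

    Records satisfy ``cost_full = icer x dalys_per_case x cases`` and
    ``dalys_full = dalys_per_case x cases`` exactly, so the net-DALY sign
    rule (net > 0 iff ICER < k) holds by construction for cost-positive
    records. Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_interventions
    icers = _log_uniform(rng, *spec.icer_range, n)
    cases = _log_uniform(rng, *spec.cases_range, n)
    dalys_per_case = _log_uniform(rng, *spec.dalys_per_case_range, n)
    levels = rng.beta(*spec.implementation_beta, size=n)
    saving = rng.random(n) < spec.cost_saving_probability
    savings_per_daly = _log_uniform(rng, *spec.savings_per_daly_range, n)

    out: list[Intervention] = []
    for i in range(n):
        dalys_full = dalys_per_case[i] * cases[i]
        if saving[i]:
            icer: float | None = None
            cost_full = -savings_per_daly[i] * dalys_full
        else:
            icer = float(icers[i])
            cost_full = icer * dalys_full
        out.append(
            Intervention(
                id=f"syn-{i + 1:03d}",
                name=f"Synthetic intervention {i + 1:03d}",
                icer_usd_per_daly=icer,
                cost_saving=bool(saving[i]),
                cases_per_year=float(cases[i]),
                cost_full_usd=float(cost_full),
                dalys_full=float(dalys_full),
                implementation_level=float(levels[i]),
            )
        )
    return out
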