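"""Independent brute-force oracles used to cross-check the fast paths."""

from itertools import combinations

from hbpkit import EconomyParams, Intervention, metrics_at_level


def net_of_subset(subset, econ: EconomyParams) -> float:
    return sum(metrics_at_level(iv, 1.0, econ).net_dalys for iv in subset)


def cost_of_subset(subset) -> float:
    return sum(iv.cost_full_usd for iv in subset)


def best_subset_exhaustive(
    interventions: list[Intervention],
    econ: EconomyParams,
    budget: float | None = None,
    forced_in: frozenset[str] = frozenset(),
    forced_out: frozenset[str] = frozenset(),
) -> tuple[frozenset[str], float]:
    """Enumerate every subset; return the feasible net-DALY maximiser.

    Feasible means: contains forced_in, avoids forced_out and (if a budget is
    given) costs no more than the budget. Intended for <= 15 interventions.
    """
    best_ids: frozenset[str] | None = None
    best_net = float("-inf")
    n = len(interventions)
    assert n <= 15, "exhaustive oracle is exponential; keep n small"
    for r in range(n + 1):
        for combo in combinations(interventions, r):
            ids = frozenset(iv.id for iv in combo)
            if not forced_in <= ids or ids & forced_out:
                continue
            if budget is not None and cost_of_subset(combo) > budget + 1e-9:
                continue
            net = net_of_subset(combo, econ)
            if net > best_net:
                best_net = net
                best_ids = ids
    assert best_ids is not None, "no feasible subset (forced set exceeds budget?)"
    return best_ids, best_net
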