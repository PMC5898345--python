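# hbpkit

A toolkit for designing **health benefits packages (HBPs)** — the set of
healthcare interventions a government commits to funding publicly — using
metrics of value founded on **health opportunity cost**. It is aimed at
health economists and analysts supporting priority-setting processes in
low- and middle-income countries, where league tables of interventions
(costs, effects, eligible populations, observed coverage) must be turned
into explicit, defensible package choices.

## The model

Each candidate intervention has an incremental cost-effectiveness ratio
(ICER, $ per DALY averted), an eligible population, a total annual cost
*C* and total DALYs averted *E* at full implementation, and an observed
implementation level ℓ ∈ [0, 1]. The system's **health opportunity cost**
is *k* ($ per DALY averted at the margin; default $61, the empirical
estimate for Malawi): a dollar spent on one intervention is a dollar not
averting 1/*k* DALYs elsewhere. Two metrics of value follow:

- **Net DALYs averted**: NHB = *E* − *C*/*k*. Cost savings (*C* < 0) add
  health, since the freed resources fund other care.
- **Financial value to the healthcare system**: NHB × *k* — the extra
  budget needed to deliver the same net health with other interventions.

From these the toolkit answers the standard package-design questions:

- **Scale** (`select_by_threshold`, `frontier_table`): include every
  cost-saving intervention and every intervention with ICER ≤ *k*; the
  package budget is an output of the threshold, not an input.
- **Best buys** (`rank_by_net_dalys`): league tables by net DALYs, which
  reflect population scale in a way ICER rankings cannot.
- **Scale-up value** (`scaleup_value`, `spending_gap`,
  `strengthening_potential`): the full-vs-actual delta per intervention is
  the most that could cost-effectively be spent removing its
  implementation constraints; aggregated, the spending gap and the maximum
  gains from health-system strengthening.
- **Expansion** (`expand_with_gap`): spending the gap on beyond-threshold
  interventions vs on implementation, with the break-even fraction of
  strengthening gains that would tip the balance.
- **Donor conditionalities & non-health objectives**
  (`conditionality_cost`, `evaluate_matched_funding`): the minimum net
  health forgone when interventions are forced in or out of a
  budget-constrained package, and accept/reject advice on matched funding.

A transcription of the published Malawi essential-health-package league
tables (67 interventions, 2014 implementation levels) ships as a built-in
worked example, and a seeded synthetic generator (`hbp synth`) emulates
the same schema for testing and simulation.

## Worked example

```python
import hbpkit as h

ivs = h.malawi_fixture()          # 67 interventions
econ = h.default_economy()        # k = $61/DALY; scenarios A/B/C

pkg = h.select_by_threshold(ivs, econ, "A")
print(len(pkg), round(pkg.budget_usd / 1e6, 1))   # 48 264.5

members = pkg.members(ivs)
rep = h.scaleup_report(members, econ)
print(round(rep.total_dalys_full / 1e6, 1),        # 49.4
      round(rep.total_dalys_actual / 1e6, 1),      # 11.4
      round(rep.spending_gap_usd / 1e6, 1))        # 197.8

exp = h.expand_with_gap(ivs, pkg, econ)
print(len(exp.added_ids),                          # 19
      round(exp.added_dalys / 1e6, 2),             # 2.74
      round(exp.forgone_vs_implementation_dalys / 1e6, 1))  # 35.3
```

At the $61 threshold, 48 of the 67 interventions enter the package, with a
full-implementation budget of $264.5M. Fully implementing them would avert
49.4M DALYs, against 11.4M at observed coverage — so health-system
strengthening could deliver up to 38M additional DALYs, and the gap
between potential and actual spend is $197.8M. Spending that gap instead
on the 19 beyond-threshold interventions (at their observed coverage)
would avert only 2.74M extra DALYs, 35.3M fewer than the
strengthening route's potential.

The same analyses are available from the shell:

```bash
hbp select --threshold-label A --out selection.json
hbp league --level full --out league.csv
hbp scaleup --out scaleup.csv
hbp expand --out expansion.json
hbp donor --scenario scenario.yaml --budget 264529527 --out donor.json
hbp synth --n 50 --seed 42 --out synth.csv
```

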