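# Methods

## Model and assumptions

The toolkit treats package design as net-health maximisation under a
marginal-productivity view of the healthcare system. The opportunity-cost
parameter *k* ($ per DALY averted at the margin) converts money into
forgone health: an intervention with total cost *C* and total DALYs
averted *E* contributes net DALYs NHB = *E* − *C*/*k*, and a financial
value NHB·*k*. Estimating *k* itself (from health-expenditure
elasticities or otherwise) is out of scope; it is a configuration input,
defaulting to $61 with alternative scenarios at $372 and $1116 (the 1× and
3× GDP-per-capita norms for Malawi).

Assumptions worth making explicit:

- **Constant returns to coverage.** Cost and DALYs scale linearly with the
  implementation level ℓ: cost ℓ·*C*, health ℓ·*E*. Published actual-level
  columns in the Malawi tables are exactly full-level × ℓ, so the fixture
  is consistent with this; real coverage-effect curves (rising marginal
  delivery costs, prevention saturation) are not modelled.
- **Indivisibility.** Interventions enter a package whole. The threshold
  package needs no divisibility assumption; the budget-capped fill
  (donor/expansion analyses) treats the marginal intervention as
  all-or-nothing.
- **Independence.** No complementarities or interactions between
  interventions: package value is the sum of member values.
- **Cost-saving services** have no defined ICER, sort before all
  cost-positive services and always belong in an unconstrained package;
  their (negative) cost adds health at rate 1/*k*.

## Selection rules

- **Threshold selection**: include all cost-saving interventions plus all
  with ICER ≤ *k*. With self-consistent inputs (*C* = ICER·*E*) this is
  the global net-DALY maximiser over all 2ⁿ subsets — the suite verifies
  this against exhaustive enumeration on small synthetic sets — and the
  budget is an *output*.
- **Ordering**: ascending ICER; ties (common when source tables print
  integer ICERs) break by the source's own cost-effectiveness rank where
  one is carried (it encodes the unrounded order; the Malawi fixture's $1
  tie between mass media and isoniazid prophylaxis is resolved this way),
  then by name, then id, so every ranking is deterministic.
- **Budget-capped greedy fill** (donor scenarios, expansion): seat
  forced-in interventions first, then fill the remaining budget in
  ascending-ICER order with candidates offering positive net health,
  skipping any that no longer fit whole (a cheaper, less cost-effective
  candidate further down may still be seated). This is a *lower bound* on
  the knapsack optimum, which suits the framework's "minimum health
  opportunity cost" reading; with a non-binding budget it coincides with
  the threshold package. Because a constrained fill can occasionally pack
  a budget better than the unconstrained one, the conditionality-cost
  comparator adopts the constrained selection whenever it scores higher —
  any package satisfying the conditions is feasible without them — keeping
  the reported cost a non-negative lower bound.
- **Conditionality comparator**: the unconstrained package is given the
  same total resources as the constrained one (budget plus any earmarked
  delta), so the measured cost is that of the *restriction*, never of the
  resources that come with it. Forced inclusion of services chosen for
  equity, continuum-of-care or complementarity reasons is priced
  identically; no multi-criteria weighting is implemented.
- **Expansion** evaluates beyond-threshold additions at their observed
  implementation levels (a config flag switches to full), and compares
  routes in gross DALYs — a deliberate best case for expansion, since
  every addition has ICER > *k* and hence negative net contribution. The
  break-even fraction is defined as added DALYs ÷ strengthening potential
  and is always computed, never quoted.

## The Malawi fixture

67 unique interventions transcribed from the published full/actual
implementation league table (duplicated rows in its fully-implemented
block are dropped, first occurrence kept), cross-checked against the
cost-effectiveness league table; the schistosomiasis mass-drug-
administration row uses the higher-precision values from the published
scale-up worked example ($76 527, 23 754 DALYs). Costs, DALYs and case
counts are printed in thousands and converted to raw units on load (the
unlabeled total-DALY column must be in thousands for the published
aggregate of 49.5M package DALYs to be reproducible — it is, to 0.1%).

Two caveats are carried explicitly:

- The **printed net-DALY columns cannot be reproduced** from the printed
  costs, DALYs and *k* = 61: they imply an internal cost basis (and an
  effective *k* ≈ 61.34) that is not published. The fixture therefore
  ships those values only inside a companion record of printed aggregates
  (`malawi_reference()`), used for differencing in the worked example and
  for cross-checks — never recomputed. For the same reason the computed
  net-DALY league agrees with the published one at the top (male
  circumcision first, obstructed-labour management second) but diverges
  for rows — notably antiretroviral therapy — whose printed totals are
  inconsistent with their printed ICERs.
- The **cotrimoxazole row** is flagged `low_confidence`: its source row
  has ambiguous column alignment (a cost-saving marker alongside a
  positive printed cost of $220k, which the cumulative-cost column
  nevertheless includes). It is kept as printed and excluded from
  exact-value tests.

## Synthetic generator

`SynthSpec` defaults describe a realistic league table: 50 interventions;
ICERs log-uniform on $1–$2000 (straddling the $61 threshold, matching the
fixture's cost-saving–$1646 span); eligible populations log-uniform on
5×10²–2×10⁷ cases (the fixture spans ~4×10² to 1.7×10⁷); DALYs per case
log-uniform on 10⁻³–10 (mass preventive through curative care);
implementation levels Beta(2, 2) (mid-range mean, full 0–1 spread, as
observed); 5% cost-saving, which save $1–$100 per DALY averted. Generated
records are *self-consistent by construction* (cost = ICER × DALYs), so
the sign rule NHB > 0 ⇔ ICER < *k* holds exactly — unlike the real
tables. Passing property tests on synthetic data therefore demonstrates
the algebra and the selection logic, not robustness to the internal
inconsistencies of real league tables, which is why fixture tests assert
printed aggregates rather than recomputed net columns. Generation is
deterministic given the seed (numpy `default_rng`).

## Numerical choices

- All arithmetic in double precision, raw USD and raw DALYs; rounding
  (integers for DALYs and $1000s) happens only in reporting.
- Package membership uses exact comparison ICER ≤ *k*; budget-fit checks
  carry a 10⁻¹² relative tolerance so a forced-in set costing exactly the
  budget is feasible.
- Degenerate inputs: an empty intervention list yields an empty selection
  with budget 0; a zero spending gap yields an empty expansion; a zero
  strengthening potential makes the break-even fraction undefined
  (signalled, not returned as 0/0); cost-saving rows raise a dedicated
  signal when a DALYs-per-$1000 ratio is requested.
- Problem sizes: fixture analyses run on all 67 interventions;
  enumeration-backed property tests use 10–12 synthetic interventions
  (≤ 4096 subsets), and property tests run 20–100 derandomised examples
  each — the full suite completes in a few seconds.

## Known limitations

- Linear coverage scaling and intervention independence, as above.
- The greedy budget-capped fill can under-fill relative to the knapsack
  optimum; reported conditionality costs are lower bounds.
- Which constraint binds implementation (demand-side, supply chain,
  staffing) and the cost-effectiveness of policies to relax it are not
  modelled; the scale-up financial value is a ceiling on such spending,
  not an estimate of it.
- Currency-year conversion and uncertainty in *k* are out of scope.
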