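{
  "k_usd_per_daly": 61.0,
  "threshold_scenarios": {
    "A": 61.0,
    "B": 372.0,
    "C": 1116.0
  },
  "package": {
    "n_interventions": 48,
    "budget_usd": 265000000.0,
    "dalys_full": 49500000.0,
    "dalys_actual": 11400000.0,
    "strengthening_potential_dalys": 38000000.0,
    "spending_gap_usd": 198000000.0
  },
  "expansion": {
    "added_dalys": 2700000.0,
    "total_dalys_with_expansion": 14200000.0,
    "forgone_vs_implementation_dalys": 35300000.0
  },
  "schistosomiasis": {
    "implementation_level": 0.13,
    "full": {
      "total_dalys": 23754.0,
      "total_cost_usd": 76527.0,
      "net_dalys": 12562.0,
      "financial_value_usd": 770567.0
    },
    "actual": {
      "total_dalys": 3088.0,
      "total_cost_usd": 9949.0,
      "net_dalys": 1633.0,
      "financial_value_usd": 100174.0
    },
    "delta": {
      "total_dalys": 20666.0,
      "total_cost_usd": 66578.0,
      "net_dalys": 10929.0,
      "financial_value_usd": 670393.0
    }
  }
}
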