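{
  "n_groups": 57,
  "n_included": 37,
  "n_excluded": 20,
  "pct_included": 65,
  "morphology_assigned_n": 2,
  "morphology_pct_assigned": 5,
  "molecular_pct_assigned": 76,
  "molecular_pct_atlantic_of_included": 57,
  "molecular_pct_pacific_of_included": 16,
  "assigned_only_pct_atlantic": 75,
  "assigned_only_pct_pacific": 21,
  "assigned_only_pct_both": 4,
  "checklist_pct_atlantic_only": 45.7,
  "checklist_pct_pacific_only": 1.7,
  "checklist_excl_arctic_pct_shared": 49,
  "checklist_excl_arctic_pct_pacific_only": 2,
  "scenario_pacific_pct_arctic_five": 33,
  "scenario_pacific_pct_plus_exemplars": 37,
  "scenario_pacific_pct_half_uncertain": 38.5,
  "scenario_pacific_pct_all_uncertain": 44
}
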