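# Published expert ratings for medium-chain acyl-CoA dehydrogenase (MCAD)
# deficiency.
disease: MCAD deficiency
selections:
  incidence: ge_1_per_100000
  early_onset: pct_1_to_30
  natural_history: clear
  disease_burden: high
  test_performance: high_sens_high_spec
  dried_blood_spot: "yes"
  throughput: ge_200_per_day
  turnaround_time: lt_1_day
  test_cost: jpy_1000_to_4999
  multiplex_capacity: ge_4
  clinical_guidelines: available
  insured_treatment: available
  early_intervention_evidence: "yes"
  follow_up_system: well_established
  consultation: available
  economic_evaluation: evidence_available
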