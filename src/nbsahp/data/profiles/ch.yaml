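# Published expert ratings for congenital hypothyroidism (CH).
disease: congenital hypothyroidism
selections:
  incidence: ge_1_per_20000
  early_onset: no_onset
  natural_history: clear
  disease_burden: high
  test_performance: high_sens_high_spec
  dried_blood_spot: "yes"
  throughput: ge_200_per_day
  turnaround_time: lt_1_day
  test_cost: lt_500_jpy
  multiplex_capacity: one
  clinical_guidelines: available
  insured_treatment: available
  early_intervention_evidence: "yes"
  follow_up_system: well_established
  consultation: available
  economic_evaluation: some_evidence
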