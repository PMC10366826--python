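# Canonical assessment hierarchy for selecting newborn-screening conditions:
# 5 categories, 16 subcategories (evaluation items), 50 criterion options.
categories:
- id: disease_condition
  label: Disease/condition
  subcategories:
  - id: incidence
    label: Incidence of the disease/condition
    description: >-
      The incidence of the disease/condition should be adequately understood.
    options:
    - {id: ge_1_per_20000, label: ">=1/20,000"}
    - {id: ge_1_per_50000, label: ">=1/50,000 but <1/20,000"}
    - {id: ge_1_per_100000, label: ">=1/100,000 but <1/50,000"}
    - {id: ge_1_per_200000, label: ">=1/200,000 but <1/100,000"}
    - {id: lt_1_per_200000, label: "<1/200,000"}
  - id: early_onset
    label: Onset of serious symptoms within 96 h of birth
    description: >-
      The incidence of serious symptoms observed before obtaining screening
      test results should be clear in order to obtain optimal outcomes for
      early detection and treatment via screening.  Dried blood specimens are
      usually collected on the 4th day after birth.
    options:
    - {id: no_onset, label: "No onset"}
    - {id: pct_1_to_30, label: ">=1% but <30%"}
    - {id: pct_30_to_70, label: ">=30% but <70%"}
    - {id: pct_70_or_unknown, label: ">=70% or unknown"}
  - id: natural_history
    label: Natural history of the disease/condition
    description: >-
      The natural history of the disease/condition and its variant forms
      should be adequately understood.
    options:
    - {id: clear, label: Clear}
    - {id: unclear, label: Unclear}
  - id: disease_burden
    label: Disease burden without treatment
    description: >-
      The disease burden of the untreated disease/condition and its variant
      forms should be adequately understood and it should be a significant
      health problem.
    options:
    - {id: high, label: High disease burden}
    - {id: moderate, label: Moderate disease burden}
    - {id: low, label: Low disease burden}
- id: screening_test
  label: Screening test
  subcategories:
  - id: test_performance
    label: Screening test performance
    description: >-
      Screening test performance should be adequately precise and validated.
    options:
    - {id: high_sens_high_spec, label: High sensitivity and specificity}
    - {id: high_sens_low_spec, label: High sensitivity but low specificity}
    - {id: others, label: The others}
  - id: dried_blood_spot
    label: Availability of dried blood specimens
    description: >-
      Collecting samples as dried blood specimens is the principal approach.
      Other specimen-collection methods should be simple and less invasive.
    options:
    - {id: "yes", label: "Yes"}
    - {id: "no", label: "No"}
  - id: throughput
    label: Number of samples that can be processed
    description: >-
      The facility performing newborn screening should be able to process a
      sufficient volume of specimens.
    options:
    - {id: ge_200_per_day, label: ">=200 samples/day/full-time equivalent (FTE)"}
    - {id: ge_100_lt_200_per_day, label: ">=100 but <200 samples/day/FTE"}
    - {id: lt_100_per_day, label: "<100 samples/day/FTE"}
  - id: turnaround_time
    label: Time to obtain screening test results
    description: >-
      The time taken to obtain screening test results should be clear.
    options:
    - {id: lt_1_day, label: "<1 day"}
    - {id: ge_1_lt_2_days, label: ">=1 but <2 days"}
    - {id: ge_2_days, label: ">=2 days"}
  - id: test_cost
    label: Cost of screening test
    description: >-
      The additional costs of introducing the screening test should be clear.
    options:
    - {id: lt_500_jpy, label: "<500 Japanese yen (JPY)"}
    - {id: jpy_500_to_999, label: "500-999 JPY"}
    - {id: jpy_1000_to_4999, label: "1000-4999 JPY"}
    - {id: ge_5000_jpy, label: ">=5000 JPY"}
  - id: multiplex_capacity
    label: Number of diseases/conditions testable at once
    description: >-
      Screening tests can measure multiple items simultaneously and should
      efficiently detect multiple diseases.
    options:
    - {id: ge_4, label: ">=4"}
    - {id: two_to_three, label: "2-3"}
    - {id: one, label: "1"}
- id: intervention
  label: Intervention
  subcategories:
  - id: clinical_guidelines
    label: Availability of clinical guidelines
    description: >-
      There should be established, evidence-based, agreed clinical guidelines
      covering cut-off points, additional testing and diagnosis for
      screen-positive subjects, intervention policies, and standard effective
      treatment strategies.
    options:
    - {id: available, label: Available}
    - {id: partially_available, label: Partially available}
    - {id: not_available, label: Not available}
  - id: insured_treatment
    label: Availability of medical interventions covered by national health insurance
    description: >-
      Participants with positive screening tests should receive appropriate
      interventions within the national health insurance system.
    options:
    - {id: available, label: Available}
    - {id: partially_available, label: Partially available}
    - {id: others, label: The others}
  - id: early_intervention_evidence
    label: Scientific evidence for the benefits of early intervention
    description: >-
      There should be scientific evidence that patients identified via
      screening can benefit from appropriate early intervention.
    options:
    - {id: "yes", label: "Yes"}
    - {id: some, label: Some}
    - {id: "no", label: "No"}
- id: follow_up
  label: Follow-up setting
  subcategories:
  - id: follow_up_system
    label: Post-screening follow-up system
    description: >-
      After diagnosis there should be a core hospital with a disease
      specialist within accessible range, and a well-established system
      coordinating the local hospital and the specialist hospital.
    options:
    - {id: well_established, label: Well established}
    - {id: partially_established, label: Partially established}
    - {id: not_established, label: Not established}
  - id: consultation
    label: Availability of post-screening consultation
    description: >-
      A nationally standardised system (genetic counselling, brochures,
      contacts for inquiries) that sufficiently explains the disease to
      screen-positive patients and their families.
    options:
    - {id: available, label: Available}
    - {id: partially_available, label: Partially available}
    - {id: not_available, label: Not available}
- id: economic_evaluation
  label: Economic evaluation
  subcategories:
  - id: economic_evaluation
    label: Economic evaluation
    description: >-
      An economic evaluation of the screening program should include
      appropriate resources used and health outcomes simultaneously,
      reflecting the national context.
    options:
    - {id: evidence_available, label: Scientific evidence is available}
    - {id: some_evidence, label: Some scientific evidence is available}
    - {id: others, label: The others}
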