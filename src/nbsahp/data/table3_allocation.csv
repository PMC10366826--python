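category_id,subcategory_id,option_id,points,provenance
disease_condition,incidence,ge_1_per_20000,10,published_table3
disease_condition,incidence,ge_1_per_50000,7,published_table3
disease_condition,incidence,ge_1_per_100000,5,published_table3
disease_condition,incidence,ge_1_per_200000,3,published_table3
disease_condition,incidence,lt_1_per_200000,2,published_table3
disease_condition,early_onset,no_onset,9,published_table3
disease_condition,early_onset,pct_1_to_30,7,published_table3
disease_condition,early_onset,pct_30_to_70,5,published_table3
disease_condition,early_onset,pct_70_or_unknown,3,published_table3
disease_condition,natural_history,clear,18,published_table3
disease_condition,natural_history,unclear,5,published_table3
disease_condition,disease_burden,high,37,published_table3
disease_condition,disease_burden,moderate,15,published_table3
disease_condition,disease_burden,low,6,published_table3
screening_test,test_performance,high_sens_high_spec,32,published_table3
screening_test,test_performance,high_sens_low_spec,10,published_table3
screening_test,test_performance,others,5,published_table3
screening_test,dried_blood_spot,yes,29,published_table3
screening_test,dried_blood_spot,no,8,published_table3
screening_test,throughput,ge_200_per_day,16,published_table3
screening_test,throughput,ge_100_lt_200_per_day,9,published_table3
screening_test,throughput,lt_100_per_day,4,published_table3
screening_test,turnaround_time,lt_1_day,17,published_table3
screening_test,turnaround_time,ge_1_lt_2_days,11,published_table3
screening_test,turnaround_time,ge_2_days,5,published_table3
screening_test,test_cost,lt_500_jpy,12,published_table3
screening_test,test_cost,jpy_500_to_999,8,published_table3
screening_test,test_cost,jpy_1000_to_4999,4,published_table3
screening_test,test_cost,ge_5000_jpy,2,published_table3
screening_test,multiplex_capacity,ge_4,16,published_table3
screening_test,multiplex_capacity,two_to_three,8,published_table3
screening_test,multiplex_capacity,one,4,published_table3
intervention,clinical_guidelines,available,39,published_table3
intervention,clinical_guidelines,partially_available,19,published_table3
intervention,clinical_guidelines,not_available,8,published_table3
intervention,insured_treatment,available,41,published_table3
intervention,insured_treatment,partially_available,17,published_table3
intervention,insured_treatment,others,8,published_table3
intervention,early_intervention_evidence,yes,104,published_table3
intervention,early_intervention_evidence,some,41,published_table3
intervention,early_intervention_evidence,no,16,published_table3
follow_up,follow_up_system,well_established,66,published_table3
follow_up,follow_up_system,partially_established,29,published_table3
follow_up,follow_up_system,not_established,11,published_table3
follow_up,consultation,available,60,published_table3
follow_up,consultation,partially_available,23,published_table3
follow_up,consultation,not_available,9,published_table3
economic_evaluation,economic_evaluation,evidence_available,114,published_table3
economic_evaluation,economic_evaluation,some_evidence,46,published_table3
economic_evaluation,economic_evaluation,others,18,published_table3
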