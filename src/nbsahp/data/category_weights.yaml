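# Published category-level weights from the group survey (printed to three
# decimals; they sum to 0.999 as printed).
disease_condition: 0.133
screening_test: 0.198
intervention: 0.292
follow_up: 0.198
economic_evaluation: 0.178
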