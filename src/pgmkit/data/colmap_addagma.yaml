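# Column map for ADDAGMA-shaped microbe-phenotype association exports.
columns:
  microbe: "Gut microbiota"
  taxonomy_rank: "Classification"
  phenotype: "Phenotype"
  condition: "Condition"
  p_value: "P-value"
  mean_ra_case: "Mean(RA)_case"
  mean_ra_control: "Mean(RA)_control"
  sampling_site: "Sample"
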