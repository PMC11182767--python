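# Column map for gutMGene-shaped microbe -> metabolite tables.
columns:
  subject: "Gut Microbiota"
  object: "Metabolite"
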