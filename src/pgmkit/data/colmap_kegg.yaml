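# Column map for KEGG compound -> pathway membership tables.
columns:
  subject: "Compound"
  object: "Pathway"
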