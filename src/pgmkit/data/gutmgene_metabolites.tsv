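Gut Microbiota	Metabolite
Blautia	Butyrate
Christensenellaceae	Butyrate
Clostridium	Butyrate
Clostridium butyricum	Butyrate
Eubacterium	Butyrate
Faecalibacterium	Butyrate
Lactobacillus	Butyrate
Clostridium	Benzoic acid
Lachnospiraceae	Benzoic acid
Oscillibacter	Benzoic acid
Prevotella	Benzoic acid
Lachnospiraceae	Chenodeoxycholic acid
Oscillibacter	Chenodeoxycholic acid
Ruminococcaceae	Chenodeoxycholic acid
Ruminococcus	Chenodeoxycholic acid
Clostridium	Deoxycholic acid
Eubacterium	12-Ketolithocholic acid
Lactobacillus	Cholic acid
Blautia	Creatine
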