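Compound	Pathway
Butyrate	Protein digestion and absorption
Creatine	Protein digestion and absorption
Butyrate	Biosynthesis of secondary metabolites
Benzoic acid	Biosynthesis of secondary metabolites
Creatine	2-Oxocarboxylic acid metabolism
Benzoic acid	2-Oxocarboxylic acid metabolism
Chenodeoxycholic acid	Primary bile acid biosynthesis
Cholic acid	Primary bile acid biosynthesis
Deoxycholic acid	Secondary bile acid biosynthesis
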