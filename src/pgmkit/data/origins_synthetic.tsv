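metabolite	host	microbiota	food
Butyrate	1	1	1
Benzoic acid	1	1	1
Chenodeoxycholic acid	1	1	1
Deoxycholic acid	1	1	1
Cholic acid	1	1	1
Creatine	1	1	1
12-Ketolithocholic acid	1	1	1
Acetate	1	1	1
Propionate	1	1	1
L-Glutamic acid	1	1	1
L-Lysine	1	1	1
Succinate	1	1	1
Lactate	1	1	1
Taurine	1	1	1
Glycine	1	1	1
Cortisol	1	0	1
Estradiol	1	0	1
Testosterone	1	0	1
Cholesterol	1	0	1
Bilirubin	1	0	1
Creatinine	1	0	1
Uric acid	1	0	1
Carnitine	1	0	1
Choline	1	0	0
Serotonin	1	0	0
Melatonin	1	0	0
Dopamine	1	0	0
Epinephrine	1	0	0
Thyroxine	1	0	0
Progesterone	1	0	0
Aldosterone	1	0	0
Indole	0	1	1
Indole-3-propionic acid	0	1	1
p-Cresol	0	1	1
Phenylacetic acid	0	1	1
Lithocholic acid	0	1	0
Trimethylamine	0	1	0
Putrescine	0	1	0
Cadaverine	0	1	0
Skatole	0	1	0
Hydrogen sulfide	0	1	0
Equol	0	1	0
Urolithin A	0	1	0
Enterolactone	0	1	0
Secoisolariciresinol	0	1	0
Desaminotyrosine	0	1	0
Imidazole propionate	0	1	0
Isovalerate	0	1	0
Isobutyrate	0	1	0
2-Methylbutyrate	0	1	0
Uncharacterized compound 1	0	0	0
Uncharacterized compound 2	0	0	0
Uncharacterized compound 3	0	0	0
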