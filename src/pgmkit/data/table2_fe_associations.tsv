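Taxonomy	PMID	MicrobiotaName	Relation	Phenotype
Genus	33839961	Anaerostipes	Positively_correlated_with	Feed efficiency
Genus	30417245	Anaerotruncus	Negatively_correlated_with	Feed efficiency
Genus	31291967	Anaerovibrio	Negatively_correlated_with	Feed efficiency
Genus	32698902	Anaerovibrio	Significantly_correlated	Feed efficiency
Species	29564121	Bacillus amyloliquefaciens	Upregulate	Feed efficiency
Family	32605690	Bacteroidaceae	Positively_correlated_with	Feed efficiency
Order	32562009	Bacteroidales	Significantly_positively_correlated	Feed efficiency
Family	30417245	Bacteroidales_S24_7_group	Negatively_correlated_with	Feed efficiency
Genus	32698902	Bacteroides	Significantly_correlated	Feed efficiency
Genus	32605690	Bacteroides	Positively_correlated_with	Feed efficiency
Genus	33123840	Barnesiella	Significantly_correlated	Feed efficiency
Genus	35528679	Bifidobacterium	Positively_correlated_with	Feed efficiency
Genus	29564121	Bifidobacterium	Significantly_positively_correlated	Feed efficiency
Genus	7	Bifidobacterium	Positively_correlated_with	Feed efficiency
Genus	32698902	Blautia	Significantly_correlated	Feed efficiency
Genus	33839961	Blautia	Positively_correlated_with	Feed efficiency
Order	33839961	Burkholderiales	Negatively_correlated_with	Feed efficiency
Genus	29746643	Campylobacter	Positively_correlated_with	Feed efficiency
Genus	30417245	Candidatus_Soleaferrea	Negatively_correlated_with	Feed efficiency
Genus	32295250	Cellulosilyticum	Positively_correlated_with	Feed efficiency
Genus	28526795	Cellulosilyticum		Feed efficiency
Family	28526795	Christensenellaceae	Positively_correlated_with	Feed efficiency
Family	30417245	Clostridiaceae_1	Positively_correlated_with	Feed efficiency
Order	32562009	Clostridiales	Significantly_positively_correlated	Feed efficiency
Genus	32698902	Clostridium	Significantly_correlated	Feed efficiency
Genus	33123840	Clostridium	Significantly_correlated	Feed efficiency
Genus	33839961	Clostridium	Negatively_correlated_with	Feed efficiency
Species	7	Clostridium butyricum	Increase	Feed efficiency
Genus	32605690	Colinsella	Significantly_positively_correlated	Feed efficiency
Family	30417245	Coriobacteriaceae	Positively_correlated_with	Feed efficiency
Family	33634901	Desulfovibrionaceae	Significantly_correlated	Feed efficiency
Genus	32698902	Dorea	Significantly_correlated	Feed efficiency
Genus	33123840	Dorea	Significantly_correlated	Feed efficiency
Genus	34438645	Dorea	Significantly_correlated	Feed efficiency
Genus	34258424	Dorea	Negatively_correlated_with	Feed efficiency
Family	32616095	Erysipelotrichaceae	Correlated_with	Feed efficiency
Genus	29746643	Escherichia	Negatively_correlated_with	Feed efficiency
Species	29564121	Escherichia coli	Significantly_negatively_correlated	Feed efficiency
Species	7	Escherichia coli	Negatively_correlated_with	Feed efficiency
Genus	33839961	Escherichia–Shigella	Negatively_correlated_with	Feed efficiency
Genus	32698902	Eubacterium	Significantly_correlated	Feed efficiency
Genus	32698902	Faecalibacterium	Significantly_correlated	Feed efficiency
Family	13	Fibrobacteraceae	Significantly_correlated	Feed efficiency
Family	33634901	Lachnospiraceae	Significantly_correlated	Feed efficiency
Family	30417245	Lachnospiraceae	Positively_correlated_with	Feed efficiency
Family	33839961	Lachnospiraceae	Positively_correlated_with	Feed efficiency
Family	33634901	Lachnospiraceae	Significantly_correlated	Feed efficiency
Genus	31291967	Lactobacillus	Positively_correlated_with	Feed efficiency
Genus	32698902	Lactobacillus	Significantly_correlated	Feed efficiency
Genus	33260665	Lactobacillus	Positively_correlated_with	Feed efficiency
Genus	33123840	Lactobacillus	Significantly_correlated	Feed efficiency
Genus	35528679	Lactobacillus	Positively_correlated_with	Feed efficiency
Genus	29564121	Lactobacillus	Significantly_positively_correlated	Feed efficiency
Genus	7	Lactobacillus	Positively_correlated_with	Feed efficiency
Genus	34438645	Lactobacillus	Significantly_correlated	Feed efficiency
Species	31291967	Lactobacillus fermentum and Pediococcus acidilactici	Increase	Feed efficiency
Species	30827387	Lactobacillus johnsonii L531	Increase	Feed efficiency
Genus	32295250	Leeia	Positively_correlated_with	Feed efficiency
Phylum	31213524	Lentisphaerae	Positively_correlated_with	Feed efficiency
Genus	33260665	Methanobrevibacter	Positively_correlated_with	Feed efficiency
Genus	31213524	Methanobrevibacter		Feed efficiency
Genus	31213524	Mucispirillum	Positively_correlated_with	Feed efficiency
Family	28526795	Nocardiaceae (Rhodococcus)	Negatively_correlated_with	Feed efficiency
Genus	36381065	Oscillibacter	Significantly_negatively_correlated	Feed efficiency
Genus	32698902	Oscillibacter	Significantly_correlated	Feed efficiency
Genus	28526795	Oscillibacter	Positively_correlated_with	Feed efficiency
Species	36381065	Paraprevotella clara	Significantly_positively_correlated	Feed efficiency
Family	30417245	Peptococcaceae	Negatively_correlated_with	Feed efficiency
Genus	34438645	Peptococcus	Significantly_correlated	Feed efficiency
Genus	32038603	Prevotella	Correlated_with	Feed efficiency
Genus	33839961	Prevotella	Positively_correlated_with	Feed efficiency
Species	34258424	Prevotella 9	Positively_correlated_with	Feed efficiency
Species	36381065	Prevotella copri	Significantly_positively_correlated	Feed efficiency
Family	33634901	Prevotellaceae	Significantly_correlated	Feed efficiency
Family	13	Prevotellaceae		Feed efficiency
Species	34258424	Prevotellaceae TCG-001	Positively_correlated_with	Feed efficiency
Family	33634901	Rikenellaceae	Significantly_correlated	Feed efficiency
Genus	32295250	Rothia	Positively_correlated_with	Feed efficiency
Genus	29746643	Ruminobacter	Negatively_correlated_with	Feed efficiency
Family	33634901	Ruminococcaceae	Significantly_correlated	Feed efficiency
Family	32616095	Ruminococcaceae	Correlated_with	Feed efficiency
Family	31213524	Ruminococcaceae	Positively_correlated_with	Feed efficiency
Genus	32698902	Ruminococcus	Significantly_correlated	Feed efficiency
Genus	13	Ruminococcus		Feed efficiency
Species	32605690	Ruminococcus flavefaciens	Positively_correlated_with	Feed efficiency
Genus	29746643	Shigella	Negatively_correlated_with	Feed efficiency
Family	33634901	Streptococcaceae	Significantly_correlated	Feed efficiency
Family	32616095	Streptococcaceae	Correlated_with	Feed efficiency
Genus	32295250	Subdoligranulu	Positively_correlated_with	Feed efficiency
Genus	33260665	Treponema	Positively_correlated_with	Feed efficiency
Species	32038603	Treponema bryantii	Correlated_with	Feed efficiency
Species	32038603	Treponema porcinum	Correlated_with	Feed efficiency
Genus	31291967	Treponema_2	Negatively_correlated_with	Feed efficiency
Genus	29746643	Veillonella	Negatively_correlated_with	Feed efficiency
Family	32616095	Veillonellaceae	Correlated_with	Feed efficiency
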