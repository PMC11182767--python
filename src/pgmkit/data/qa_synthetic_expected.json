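{
 "Which microbes are significantly positively correlated with feed efficiency?": [
  "Bacteroidales",
  "Bifidobacterium",
  "Clostridiales",
  "Colinsella",
  "Lactobacillus",
  "Paraprevotella clara",
  "Prevotella copri"
 ],
 "Which microbes produce butyrate?": [
  "Blautia",
  "Christensenellaceae",
  "Clostridium",
  "Clostridium butyricum",
  "Eubacterium",
  "Faecalibacterium",
  "Lactobacillus"
 ],
 "Which microbes are associated with fermented spent mushroom substrates?": [
  "Clostridium disporicum",
  "Lactobacillus gasseri",
  "Roseburia",
  "Streptococcus",
  "Lactobacillus",
  "Bacteroidetes",
  "Firmicutes"
 ],
 "Which microbes are associated with the Duroc x Large White x Landrace breed?": [
  "Bacteroidetes",
  "Firmicutes"
 ],
 "Which metabolites does Blautia produce?": [
  "Butyrate",
  "Creatine"
 ],
 "Which pathways involve benzoic acid?": [
  "Biosynthesis of secondary metabolites",
  "2-Oxocarboxylic acid metabolism"
 ],
 "Which microbes produce chenodeoxycholic acid?": [
  "Lachnospiraceae",
  "Oscillibacter",
  "Ruminococcaceae",
  "Ruminococcus"
 ],
 "Which microbe upregulates feed efficiency significantly?": [
  "Bacillus amyloliquefaciens"
 ],
 "Which microbes are significantly negatively associated with feed efficiency?": [
  "Escherichia coli",
  "Oscillibacter"
 ],
 "Which probiotic combination increases feed efficiency?": [
  "Lactobacillus fermentum and Pediococcus acidilactici"
 ],
 "What taxonomy rank does Lactobacillus belong to?": [
  "Genus"
 ],
 "What taxonomy rank does Bacteroidales belong to?": [
  "Order"
 ],
 "What taxonomy rank does Lachnospiraceae belong to?": [
  "Family"
 ],
 "What taxonomy rank does Lentisphaerae belong to?": [
  "Phylum"
 ],
 "Which microbe is most frequently linked to feed efficiency in the curated literature?": [
  "Lactobacillus"
 ],
 "Which experiment design uses fermented spent mushroom substrates?": [
  "fed basal diets supplemented with 3% FSMS"
 ],
 "Which experiment group was fed basal diets supplemented with 3% FSMS?": [
  "FSMS"
 ],
 "Which pathway do butyrate and creatine share?": [
  "Protein digestion and absorption"
 ],
 "Which bile acids are involved in primary bile acid biosynthesis?": [
  "Chenodeoxycholic acid",
  "Cholic acid"
 ],
 "Which microbes produce benzoic acid?": [
  "Clostridium",
  "Lachnospiraceae",
  "Oscillibacter",
  "Prevotella"
 ],
 "Which Lactobacillus strain increases feed efficiency?": [
  "Lactobacillus johnsonii L531"
 ],
 "Which microbe produces 12-ketolithocholic acid?": [
  "Eubacterium"
 ],
 "Which microbes are negatively correlated with feed efficiency according to PMID 29746643?": [
  "Escherichia",
  "Ruminobacter",
  "Shigella",
  "Veillonella"
 ],
 "Which microbes did PMID 32038603 report as correlated with feed efficiency?": [
  "Prevotella",
  "Treponema bryantii",
  "Treponema porcinum"
 ],
 "Which Treponema taxa correlate with feed efficiency?": [
  "Treponema",
  "Treponema bryantii",
  "Treponema porcinum",
  "Treponema_2"
 ],
 "Which microbe produces cholic acid?": [
  "Lactobacillus"
 ],
 "Which sampling sites are typical for gut microbiota studies in pigs?": [
  "feces",
  "ileum",
  "cecum",
  "colon"
 ],
 "Which phylum-level microbes respond to oregano and tributyrin supplementation?": [
  "Bacteroidetes",
  "Firmicutes"
 ],
 "Which microbes were positively correlated with feed efficiency in PMID 32295250?": [
  "Cellulosilyticum",
  "Leeia",
  "Rothia",
  "Subdoligranulu"
 ],
 "Which archaeon is positively correlated with feed efficiency?": [
  "Methanobrevibacter"
 ]
}
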