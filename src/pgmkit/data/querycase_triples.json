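[
 {
  "Triple_list": {
   "relation": "belong_to",
   "object_type": "ExperimentDesign",
   "subject_type": "FeedFermentationType",
   "object": "fed basal diets supplemented with 3% FSMS",
   "subject": "fermented spent mushroom substrates"
  }
 },
 {
  "Triple_list": {
   "relation": "belong_to",
   "object_type": "ExperimentDesign",
   "subject_type": "ExperimentGroup",
   "object": "fed basal diets supplemented with 3% FSMS",
   "subject": "FSMS"
  }
 },
 {
  "Triple_list": {
   "relation": "influence",
   "object_type": "MicrobiotaName",
   "subject_type": "ExperimentGroup",
   "object": "Clostridium disporicum",
   "subject": "FSMS"
  }
 },
 {
  "Triple_list": {
   "relation": "influence",
   "object_type": "MicrobiotaName",
   "subject_type": "ExperimentGroup",
   "object": "Lactobacillus gasseri",
   "subject": "FSMS"
  }
 },
 {
  "Triple_list": {
   "relation": "influence",
   "object_type": "MicrobiotaName",
   "subject_type": "ExperimentGroup",
   "object": "Roseburia",
   "subject": "FSMS"
  }
 },
 {
  "Triple_list": {
   "relation": "influence",
   "object_type": "MicrobiotaName",
   "subject_type": "ExperimentGroup",
   "object": "Streptococcus",
   "subject": "FSMS"
  }
 },
 {
  "Triple_list": {
   "relation": "influence",
   "object_type": "MicrobiotaName",
   "subject_type": "ExperimentGroup",
   "object": "Lactobacillus",
   "subject": "FSMS"
  }
 },
 {
  "Triple_list": {
   "relation": "influence",
   "object_type": "MicrobiotaName",
   "subject_type": "ExperimentGroup",
   "object": "Bacteroidetes",
   "subject": "FSMS"
  }
 },
 {
  "Triple_list": {
   "relation": "influence",
   "object_type": "MicrobiotaName",
   "subject_type": "ExperimentGroup",
   "object": "Firmicutes",
   "subject": "FSMS"
  }
 },
 {
  "Triple_list": {
   "relation": "belong_to",
   "object_type": "SwineBreed",
   "subject_type": "ExperimentDesign",
   "object": "Duroc × Large White × Landrace",
   "subject": "control plus oregano and tributyrin"
  }
 },
 {
  "Triple_list": {
   "relation": "belong_to",
   "object_type": "SwineBreed",
   "subject_type": "ExperimentDesign",
   "object": "Duroc × Large White × Landrace",
   "subject": "control plus methyl salicylate and tributyrin"
  }
 },
 {
  "Triple_list": {
   "relation": "belong_to",
   "object_type": "SwineBreed",
   "subject_type": "ExperimentDesign",
   "object": "Duroc × Large White × Landrace",
   "subject": "control plus antibiotics"
  }
 },
 {
  "Triple_list": {
   "relation": "belong_to",
   "object_type": "SwineBreed",
   "subject_type": "ExperimentDesign",
   "object": "Duroc × Large White × Landrace",
   "subject": "basal diet"
  }
 },
 {
  "Triple_list": {
   "relation": "belong_to",
   "object_type": "ExperimentDesign",
   "subject_type": "ExperimentGroup",
   "object": "control plus oregano and tributyrin",
   "subject": "OT"
  }
 },
 {
  "Triple_list": {
   "relation": "influence",
   "object_type": "MicrobiotaName",
   "subject_type": "ExperimentGroup",
   "object": "Bacteroidetes",
   "subject": "OT"
  }
 },
 {
  "Triple_list": {
   "relation": "influence",
   "object_type": "MicrobiotaName",
   "subject_type": "ExperimentGroup",
   "object": "Firmicutes",
   "subject": "OT"
  }
 }
]
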