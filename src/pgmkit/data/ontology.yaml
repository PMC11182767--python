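# Default domain ontology for the pig-gut-microbiota / feed-efficiency knowledge graph.
# 11 entity classes, each with its detail (node-label) types, and the closed relation
# vocabulary grouped by relation category.
name: pig-gut-microbiota
classes:
  Swine:
    - SwineBreed
    - SwineSex
    - SwineWeight
    - SwineAge
    - SwineStage
    - SwinePlace
    - SwineType
  Microbiota:
    - MicrobiotaName
    - MicrobiotaTaxonomy
    - MicrobiotaDiversity
    - MicrobiotaType
  FeedEfficiency:
    - FeedEfficiency
    - ResidualFeedIntake
    - FeedConversionRatio
  Performance:
    - CarcassTraits
    - GrowthPerformance
    - SerumIndex
    - AcidType
    - DigestibilityType
    - UtilizationefficiencyType
    - ConcentrationType
    - AminoacidType
    - AminoacidName
    - CellType
    - CellName
  Gene:
    - GeneType
    - GeneName
  Protein:
    - ProteinType
    - ProteinName
  Metabolism:
    - MetabolismType
    - MetabolismName
    - MetabolitesType
    - MetabolitesName
  Experiment:
    - ExperimentDesign
    - ExperimentGroup
    - ExperimentDays
    - SamplingSites
    - SamplingTissues
    - SamplingType
  Feed:
    - DietType
    - NutrientType
    - FeedsubstituteType
    - FeedsubstituteName
    - SubstituteAmount
    - FeedingredientName
    - FeedingredientType
    - FeedFermentationType
    - Antibiotic
    - StarchType
    - FeedadditivesType
    - FeedadditivesName
    - AntibioticSubstituteName
    - AntibioticSubstituteType
  Disease:
    - DiseaseName
    - DiseaseType
  Environment:
    - VaccineType
    - WaterTemperature
    - ConditionTemperature
    - ContaminantType
    - ContaminantName
relations:
  sameAs:
    - equal_to
    - similar
  hasProperty:
    - has_Time
    - has_Breed
    - has_Stage
    - has_Sex
    - has_Age
    - has_Day
    - has_Weight
    - has_Amonut
    - has_Place
    - has_Food
  subClassOf:
    - belong_to
  regulation:
    - increase
    - decrease
    - upregulate
    - downregulate
  treatment_effect:
    - significantly_positively_correlated
    - significantly_negatively_correlated
    - significantly_correlated
    - correlated_with
    - positively_correlated_with
    - negatively_correlated_with
    - modulate
    - involved_in
    - is_carried_out_by
    - express
    - influence
    - noinfluence
    - located_in
    - vaccinated_with
    - inhibite
    - dominated
    - followed
    - feed
    - produce
  comparison:
    - higher
    - heavier
    - highest
    - intermediate
    - significantly_higher
    - lower
    - lowest
    - high_diversity
    - significant_diferences
    - nosignifcant_diferences
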