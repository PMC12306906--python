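{
  "format_version": "1.0",
  "tables": {
    "registry.csv": "segment registry: one row per unique basic phantom segment (289 rows)",
    "microstructure.csv": "BV/TV, Tb.Th, Tb.Sp population means and SDs by site/group/age",
    "cvis.csv": "intra-specimen coefficients of variation (%) by bone group",
    "densities.csv": "mineralised-bone and marrow densities (g/cm^3) by reference age",
    "dimensions.csv": "segment dimensions and cortical thickness (mm); partial coverage, synthetic where no printed value exists (see docs/methods.md)"
  },
  "ages": [
    "0-Y",
    "1-Y",
    "5-Y",
    "10-Y",
    "15-Y",
    "adult"
  ],
  "label_codes": {
    "outside": 0,
    "marrow": 1,
    "trabecula": 2,
    "cortical": 3
  }
}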