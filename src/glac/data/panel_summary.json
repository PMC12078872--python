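{
  "description": "Allele-change tallies for the 750-accession Chinese soybean germplasm panel (127 wild accessions, 424 landraces, 199 released cultivars): 154,088 SNPLDB loci carrying 559,611 haplotype alleles, compared across domestication (WA->LR, ~5000 years) and modern breeding (LR->RC, ~100 years).",
  "allele_universe": 559611,
  "locus_universe": 154088,
  "transitions": {
    "WA->LR": {
      "years": 5000,
      "counts": {
        "inherited_fixed": 37,
        "inherited_LPD": 23670,
        "inherited_LPE": 2351,
        "inherited_increase": 206020,
        "inherited_decrease": 212521,
        "excluded": 76866,
        "emerged": 37543,
        "absent_both": 603
      }
    },
    "LR->RC": {
      "years": 100,
      "counts": {
        "inherited_fixed": 22261,
        "inherited_LPD": 23971,
        "inherited_LPE": 37,
        "inherited_LPR": 1409,
        "inherited_increase": 175203,
        "inherited_decrease": 179688,
        "excluded": 79573,
        "emerged": 603,
        "restored": 6238,
        "absent_both": 70628
      }
    }
  },
  "chained": {
    "excluded_then_absent": 70628,
    "emerged_then_inherited": 35690,
    "loci_fixed_both_stages": 22261,
    "loci_lpd_after_increase": 23571,
    "loci_fixed_in_final_stage": 46232
  }
}
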