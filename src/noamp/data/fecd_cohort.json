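{
  "description": "Published per-sample summary values for an 11-sample FECD cohort genotyped at the TCF4 CTG18.1 locus (with FMR1 as multiplexed control) by amplification-free Cas9-targeted SMRT sequencing at the 99% similarity filter. 'NI' marks values the assay could not identify; STR genotypes prefixed '>=' are lower bounds from fragment analysis.",
  "snp": "rs599550",
  "expansion_threshold": 50,
  "control_threshold": 55,
  "samples": [
    {
      "sample_id": "1", "category": "A", "on_target_tcf4": 761, "on_target_fmr1": 204,
      "phase_method": "None", "snp_genotype": "T/T",
      "alleles": [
        {"phased_reads": null, "mode": 11, "ctc": 13, "mean": null, "size_range": null, "max": null, "str_genotype": "12", "fmr1_cgg": 27},
        {"phased_reads": null, "mode": 14, "ctc": 13, "mean": null, "size_range": null, "max": null, "str_genotype": "15", "fmr1_cgg": 29}
      ]
    },
    {
      "sample_id": "2", "category": "A", "on_target_tcf4": 1166, "on_target_fmr1": 323,
      "phase_method": "SNP", "snp_genotype": "A/T",
      "alleles": [
        {"phased_reads": 445, "mode": 25, "ctc": 13, "mean": 25, "size_range": 9, "max": 30, "str_genotype": "26", "fmr1_cgg": 28},
        {"phased_reads": 416, "mode": 30, "ctc": 13, "mean": 30, "size_range": 9, "max": 37, "str_genotype": "31", "fmr1_cgg": 34}
      ]
    },
    {
      "sample_id": "3", "category": "B", "on_target_tcf4": 970, "on_target_fmr1": 237,
      "phase_method": "SNP", "snp_genotype": "A/T",
      "alleles": [
        {"phased_reads": 358, "mode": 23, "ctc": 13, "mean": 23, "size_range": 14, "max": 25, "str_genotype": "24", "fmr1_cgg": 28},
        {"phased_reads": 375, "mode": 70, "ctc": 13, "mean": 71, "size_range": 25, "max": 90, "str_genotype": "71", "fmr1_cgg": 32}
      ]
    },
    {
      "sample_id": "4", "category": "B", "on_target_tcf4": 1011, "on_target_fmr1": 107,
      "phase_method": "CTC length and SNP", "snp_genotype": "A/T",
      "alleles": [
        {"phased_reads": 408, "mode": 23, "ctc": 13, "mean": 24, "size_range": 59, "max": 81, "str_genotype": "24", "fmr1_cgg": 27},
        {"phased_reads": 363, "mode": 73, "ctc": 14, "mean": 72, "size_range": 66, "max": 115, "str_genotype": "72", "fmr1_cgg": 27}
      ]
    },
    {
      "sample_id": "5", "category": "B", "on_target_tcf4": 1205, "on_target_fmr1": 153,
      "phase_method": "CTC length and SNP", "snp_genotype": "A/T",
      "alleles": [
        {"phased_reads": 378, "mode": 11, "ctc": 13, "mean": 11, "size_range": 2, "max": 12, "str_genotype": "12", "fmr1_cgg": 22},
        {"phased_reads": 496, "mode": 80, "ctc": 14, "mean": 82, "size_range": 98, "max": 169, "str_genotype": "79", "fmr1_cgg": 22}
      ]
    },
    {
      "sample_id": "6", "category": "B", "on_target_tcf4": 293, "on_target_fmr1": 115,
      "phase_method": "CTC", "snp_genotype": "T/T",
      "alleles": [
        {"phased_reads": 157, "mode": 32, "ctc": 12, "mean": 36, "size_range": 614, "max": 645, "str_genotype": "32", "fmr1_cgg": 28},
        {"phased_reads": 38, "mode": 110, "ctc": 13, "mean": 171, "size_range": 466, "max": 566, "str_genotype": "109", "fmr1_cgg": 28}
      ]
    },
    {
      "sample_id": "7", "category": "B", "on_target_tcf4": 783, "on_target_fmr1": 250,
      "phase_method": "CTC", "snp_genotype": "T/T",
      "alleles": [
        {"phased_reads": 359, "mode": 17, "ctc": 13, "mean": 17, "size_range": 2, "max": 18, "str_genotype": "18", "fmr1_cgg": 28},
        {"phased_reads": 157, "mode": 131, "ctc": 8, "mean": 425, "size_range": 1244, "max": 1361, "str_genotype": "124", "fmr1_cgg": 28}
      ]
    },
    {
      "sample_id": "8", "category": "C", "on_target_tcf4": 982, "on_target_fmr1": 240,
      "phase_method": "CTC length and SNP", "snp_genotype": "A/T",
      "alleles": [
        {"phased_reads": 376, "mode": 80, "ctc": 15, "mean": 82, "size_range": 46, "max": 106, "str_genotype": "81", "fmr1_cgg": 24},
        {"phased_reads": 367, "mode": 102, "ctc": 11, "mean": 126, "size_range": 412, "max": 498, "str_genotype": ">=81", "fmr1_cgg": 28}
      ]
    },
    {
      "sample_id": "9", "category": "C", "on_target_tcf4": 595, "on_target_fmr1": 195,
      "phase_method": "CTC", "snp_genotype": "A/A",
      "alleles": [
        {"phased_reads": 357, "mode": 72, "ctc": 14, "mean": 74, "size_range": 170, "max": 236, "str_genotype": "72", "fmr1_cgg": 28},
        {"phased_reads": 83, "mode": 118, "ctc": 12, "mean": 272, "size_range": 1524, "max": 1593, "str_genotype": ">=72", "fmr1_cgg": 29}
      ]
    },
    {
      "sample_id": "10", "category": "C", "on_target_tcf4": 1244, "on_target_fmr1": 326,
      "phase_method": "SNP", "snp_genotype": "A/T",
      "alleles": [
        {"phased_reads": 574, "mode": 69, "ctc": 13, "mean": 70, "size_range": 35, "max": 89, "str_genotype": "70", "fmr1_cgg": 28},
        {"phased_reads": 391, "mode": 91, "ctc": 13, "mean": 175, "size_range": 926, "max": 1014, "str_genotype": ">=70", "fmr1_cgg": 37}
      ]
    },
    {
      "sample_id": "11", "category": "C", "on_target_tcf4": 861, "on_target_fmr1": 132,
      "phase_method": "None", "snp_genotype": "T/T",
      "alleles": [
        {"phased_reads": null, "mode": 79, "ctc": 12, "mean": null, "size_range": null, "max": null, "str_genotype": "76", "fmr1_cgg": 28},
        {"phased_reads": null, "mode": 141, "ctc": 12, "mean": null, "size_range": null, "max": null, "str_genotype": ">=76", "fmr1_cgg": 28}
      ]
    }
  ]
}
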