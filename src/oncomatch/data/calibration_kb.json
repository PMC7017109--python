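{
 "version": "calibration-1",
 "drugs": [
  {"drug_id": "anastrozole", "name": "Anastrozole", "drug_class": "hormone", "adult_only": false, "routes": ["oral"], "contraindication_flags": []},
  {"drug_id": "capecitabine", "name": "Capecitabine", "drug_class": "cytotoxic", "adult_only": false, "routes": ["oral"], "contraindication_flags": []},
  {"drug_id": "cisplatin", "name": "Cisplatin", "drug_class": "cytotoxic", "adult_only": false, "routes": ["iv"], "contraindication_flags": []},
  {"drug_id": "cyclophosphamide", "name": "Cyclophosphamide", "drug_class": "cytotoxic", "adult_only": false, "routes": ["iv", "oral"], "contraindication_flags": []},
  {"drug_id": "doxorubicin", "name": "Doxorubicin", "drug_class": "cytotoxic", "adult_only": false, "routes": ["iv"], "contraindication_flags": ["cardiomyopathy"]},
  {"drug_id": "everolimus", "name": "Everolimus", "drug_class": "targeted_small_molecule", "adult_only": false, "routes": ["oral"], "contraindication_flags": []},
  {"drug_id": "fluorouracil", "name": "Fluorouracil", "drug_class": "cytotoxic", "adult_only": false, "routes": ["iv"], "contraindication_flags": []},
  {"drug_id": "paclitaxel", "name": "Paclitaxel", "drug_class": "cytotoxic", "adult_only": false, "routes": ["iv"], "contraindication_flags": []},
  {"drug_id": "tamoxifen", "name": "Tamoxifen", "drug_class": "hormone", "adult_only": false, "routes": ["oral"], "contraindication_flags": []},
  {"drug_id": "trastuzumab", "name": "Trastuzumab", "drug_class": "antibody", "adult_only": false, "routes": ["iv"], "contraindication_flags": ["cardiomyopathy"]}
 ],
 "pathways": [
  {"pathway_id": "PI3K_AKT_MTOR", "member_genes": ["AKT1", "MTOR", "PTEN"]},
  {"pathway_id": "HORMONE_SIGNALING", "member_genes": ["ER", "PR"]},
  {"pathway_id": "CELL_CYCLE", "member_genes": ["CCND1", "TP53"]},
  {"pathway_id": "RTK_RAS_MAPK", "member_genes": ["FGFR1", "KRAS", "MYC"]}
 ],
 "rules": [
  {"drug_id": "tamoxifen", "gene": "ER", "alteration_class": "expression_positive", "match_type": "direct", "weight_override": null, "evidence_tag": "sensitivity_biomarker"},
  {"drug_id": "anastrozole", "gene": "ER", "alteration_class": "expression_positive", "match_type": "direct", "weight_override": null, "evidence_tag": "sensitivity_biomarker"},
  {"drug_id": "anastrozole", "gene": "PR", "alteration_class": "expression_positive", "match_type": "indirect", "weight_override": null, "evidence_tag": "pathway"},
  {"drug_id": "everolimus", "gene": "PTEN", "alteration_class": "copy_loss", "match_type": "direct", "weight_override": null, "evidence_tag": "sensitivity_biomarker"},
  {"drug_id": "trastuzumab", "gene": "ERBB2", "alteration_class": "amplification", "match_type": "direct", "weight_override": null, "evidence_tag": "antibody_epitope"}
 ]
}
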