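{
  "note": "Verbatim extracted-table strings before tokenization/decimal conversion. Rating-panel and comparison-panel term strings are concatenated in the extracted text; they were resolved once with a deterministic tokenizer (exact token count, greedy longest match with backtracking). Rows EAM1/DM1, EAM1/DM2, EAM2/DM3, EAM4/DM1 and EAM5/DM2 admit more than one 12-token reading; the tokenizer's reading was frozen into rating_panel.csv.",
  "rating_panel_strings": {
    "EAM1/DM1": "MHMHHHMLVHLMMHMHL",
    "EAM1/DM2": "MHHHVHMHMHMLMHHHL",
    "EAM1/DM3": "HVHHHVHMLHLMHVHHML",
    "EAM2/DM1": "MLVHHMHMHMVHLMHMHMHL",
    "EAM2/DM2": "MHVHHMHHMLVHMLMHHHML",
    "EAM2/DM3": "MHVHHVHMLHLHVHHML",
    "EAM3/DM1": "MHVHVHHVHMLVHLMHMHMHML",
    "EAM3/DM2": "HVHVHHVHMLVHMLHMHHML",
    "EAM3/DM3": "MHVHVHHHMLVHLHMHMHML",
    "EAM4/DM1": "MHMHMHHMLMHLMMHMHML",
    "EAM4/DM2": "MHHHMHMHMLHMLMMHMHML",
    "EAM4/DM3": "MMHMHMHMHMLHLMHHHML",
    "EAM5/DM1": "MHHHHMHMMHMLMHHMHML",
    "EAM5/DM2": "HVHVHHHMHMLMHVHMHL",
    "EAM5/DM3": "MHVHHHHMLHLMHVHHML",
    "EAM6/DM1": "MLMMHMHHMLMHMLMHMMHML",
    "EAM6/DM2": "MMHMMMHLHMLMMHMHML",
    "EAM6/DM3": "MLMHMMHMHLHMLMMHMHL"
  },
  "forward_panel_strings": {
    "C2": "MSMMDM",
    "C3": "MDMMSM",
    "C4": "SMMDMM",
    "C5": "MMSMMDM",
    "C6": "SMMDMM",
    "C7": "MDMMSM",
    "C8": "SMSMSM",
    "C9": "MMMMM",
    "C10": "SMMMDM",
    "C11": "MMSM",
    "C12": "SMSMSM"
  },
  "inverse_panel_strings": {
    "C11": "MDLMDLWL",
    "C10": "MDLLMDL",
    "C9": "LRLMDL",
    "C8": "WLMDLMDL",
    "C7": "WLMDLMDM",
    "C6": "MDLLL",
    "C5": "WLWLMDM",
    "C4": "LWLMDM",
    "C3": "LMDLMDM",
    "C2": "MDLMDLWL",
    "C1": "MDLWLMDL"
  },
  "decimal_comma_examples": [
    "69,14",
    "0,5581",
    "0,101"
  ]
}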