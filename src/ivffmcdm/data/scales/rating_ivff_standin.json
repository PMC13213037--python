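{
  "name": "rating_ivff_standin",
  "role": "rating",
  "q": 3,
  "note": "SYNTHETIC STAND-IN rating scale. A symmetric 7-term interval-valued Fermatean fuzzy ladder in the style of published IVFF rating scales; it is NOT the supplementary scale of the case study this package emulates. Replace this file (same format) to use a different scale.",
  "terms": [
    {"term": "VL", "mu": [0.05, 0.15], "nu": [0.85, 0.95]},
    {"term": "L",  "mu": [0.15, 0.30], "nu": [0.70, 0.85]},
    {"term": "ML", "mu": [0.30, 0.45], "nu": [0.55, 0.70]},
    {"term": "M",  "mu": [0.45, 0.55], "nu": [0.45, 0.55]},
    {"term": "MH", "mu": [0.55, 0.70], "nu": [0.30, 0.45]},
    {"term": "H",  "mu": [0.70, 0.85], "nu": [0.15, 0.30]},
    {"term": "VH", "mu": [0.85, 0.95], "nu": [0.05, 0.15]}
  ]
}
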