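{
  "name": "comparison_ivff_standin",
  "role": "comparison",
  "q": 3,
  "note": "SYNTHETIC STAND-IN comparison scale for sequential pairwise criterion weighting. A symmetric 9-term interval-valued Fermatean fuzzy ladder around the 'equal importance' pivot; it is NOT the supplementary scale of the case study this package emulates. Replace this file (same format) to use a different scale.",
  "terms": [
    {"term": "L",   "group": "less",  "mu": [0.15, 0.25], "nu": [0.75, 0.85]},
    {"term": "MDL", "group": "less",  "mu": [0.25, 0.35], "nu": [0.65, 0.75]},
    {"term": "RL",  "group": "less",  "mu": [0.30, 0.40], "nu": [0.60, 0.70]},
    {"term": "WL",  "group": "less",  "mu": [0.35, 0.45], "nu": [0.55, 0.65]},
    {"term": "M",   "group": "equal", "mu": [0.45, 0.55], "nu": [0.45, 0.55]},
    {"term": "SM",  "group": "more",  "mu": [0.55, 0.65], "nu": [0.35, 0.45]},
    {"term": "MDM", "group": "more",  "mu": [0.65, 0.75], "nu": [0.25, 0.35]},
    {"term": "MM",  "group": "more",  "mu": [0.75, 0.85], "nu": [0.15, 0.25]},
    {"term": "AM",  "group": "more",  "mu": [0.85, 0.95], "nu": [0.05, 0.15]}
  ]
}
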