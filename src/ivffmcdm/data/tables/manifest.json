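{
  "piprecia_forward.csv": {
    "rows": 12,
    "cols": 4,
    "sha256": "8fe752af09d4e451b5099460a2d73ab1bf9e5df28dfa4d14b64fc2e13993de4b"
  },
  "piprecia_inverse.csv": {
    "rows": 12,
    "cols": 4,
    "sha256": "4d2c48c4837e79ada6362b350c5c25204547dcb7048834363af9e791100f2e10"
  },
  "rating_panel.csv": {
    "rows": 18,
    "cols": 14,
    "sha256": "9453eca359d49c6bd37cd34b6f35049d3ab4a939a4878ca27a0d51f33dafd6a0"
  },
  "mairca_q.csv": {
    "rows": 6,
    "cols": 2,
    "sha256": "4d677d457fc9fcfd93698f4815e76dae33475dca40bbef20fbb2d4573aa30977"
  },
  "score_matrix.csv": {
    "rows": 6,
    "cols": 24,
    "sha256": "26ac2fd3ae1d5e2584152621b13036a18c40263619dece310d2cecd61745c98d"
  },
  "entropy_table.csv": {
    "rows": 23,
    "cols": 4,
    "sha256": "4628d6af23d4605e3699f3575cd1883e65b715efa5dc38e959883fa42bf5ba7f"
  },
  "framework_weights.csv": {
    "rows": 12,
    "cols": 7,
    "sha256": "7d26683769575215978b0e2caf6333bdbde4a78a2ee7523d8183086a8f182202"
  },
  "framework_ranks.csv": {
    "rows": 6,
    "cols": 7,
    "sha256": "2b36f13f8da54467cb68c0854c14a78e95688471c99c163e6335d5b78ee6d03b"
  }
}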