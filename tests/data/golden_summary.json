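{
  "config_sha256": "f213c8c2cf4233ad",
  "n_called": 80,
  "n_clones": 80,
  "n_rejected": 0,
  "stats": {
    "best_threshold": 36,
    "fisher_p": 0.015660929311394296,
    "odds_ratio": 0.10833333333333334,
    "table": {
      "n11": 1,
      "n12": 15,
      "n21": 24,
      "n22": 39
    },
    "threshold": 40
  },
  "version": "0.1.0"
}
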