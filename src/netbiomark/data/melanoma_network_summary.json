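{
  "description": "Whole-network summary statistics of the published melanoma stem-cell-pluripotency + calcium-signaling interactome from which the 27-gene central-node table derives; used for worked examples and regression checks.",
  "n_nodes": 294,
  "n_edges": 2995,
  "degree": {"mean": 20.37414, "sd": 16.80553, "threshold": 37.17968},
  "betweenness": {"mean": 0.00656, "sd": 0.01276070, "threshold": 0.01932203},
  "datasets": ["GSE8401", "GSE46517", "GSE15605"],
  "alpha": 0.05
}
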