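# End-to-end demo: simulate a two-species RAD study under a secondary
# contact history, then run the full divergence-landscape analysis.
# Runs in a few minutes on one CPU.
seed: 7
simulate:
  enabled: true
  model: SCS
  samples: [20, 10]
  n_loci: 240
  theta: 4.0
filters: {}
demography:
  enabled: true
  projection: [20, 10]
  n_loci: 400
  restarts: 1
  cycles: 12
  final_n_loci: 1500
  models: [SI, IM, SCS]
  # the generator's per-locus mutation rate: theta / (4 N_pma)
  anchor_mu: 0.002
  anchor_loci: 240
windows:
  window: 100000
  min_snps: 5
  quantile: 0.95
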