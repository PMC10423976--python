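# Full pipeline configuration for `phenoproc run-all`.
# Reduced annealing budget so the run finishes in a few minutes; production
# fits use chains: 25 and iterations: 40000.
seed: 11
simulate:
  n_years: 3
  pfts: [DN]
fit:
  models: [TT, PTT, LIN]
  season: spring
  pft: DN
  chains: 3
  iterations: 1000
depth_scan:
  channels: [air, 0, 10, 50, 200]
sensitivity: true
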