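# Demo pipeline configuration: a synthetic cohort with the package's
# reference study conditions, screened end to end.
generator:
  n_participants: 1128
  seed: 7
  invalid_rate: 0.0
hmm:
  n_states: 3
  n_restarts: 3
  max_iter: 300
  tol: 1.0e-6
  seed: 7
  decode: gamma_argmax
grouping:
  high_cut: 20
  low_cut: 10
baselines:
  methods: [kmeans, gmm, agglomerative, spectral]
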