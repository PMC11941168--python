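# Default demonstration workflow: 500 genes, a planted 10-gene DNB module,
# five ordered stages approaching the stability boundary, 8 samples/stage.
simulate:
  n_genes: 500
  dnb_size: 10
  intra_coupling: 1.0
  schedule: [0.1, 0.3, 0.5, 0.7, 0.95]
  n_samples: 8
  meas_noise_sd: 0.1
  seed: 42
detect:
  sd_fold_min: 1.5
  corr_link_min: 0.6
  eps: 1.0e-06
  peak_ratio_min: 2.0
  log2: false
rank:
  k: 10
  select: topk
intervene:
  strength: 0.5
  n_draws: 100
  seed: 7
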