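# Small end-to-end demo: simulate a synthetic collection and run every stage.
seed: 1
simulate:
  n_pops: 8
  n_per_pop: 8
  n_loci: 600
  n_chrom: 4
  chrom_length_bp: 10000000
  fst: 0.3
  n_adaptive: 10
  adaptive_slope: 1.5
  block_len_bp: 50000
stages:
  qc: true
  structure: true
  tree: true
  dapc: true
  gea: true
  ld: true
  pheno: true
  regress: true
structure:
  kmin: 1
  kmax: 4
  runs: 3
  n_init: 1
  max_iter: 300
  tol: 1.0e-5
tree:
  boot: 200
dapc:
  max_k: 5
ld:
  max_dist: 300000
  bin: 20000
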