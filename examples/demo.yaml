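populations:
  - {label: A, n_samples: 300, ancestry_fst: 0.1}
  - {label: B, n_samples: 300, ancestry_fst: 0.1}
n_genes: 60
n_snps_per_gene: 60
n_causal: 3
rho_effects: 0.8
n_pcs: 3
n_hidden_factors: 10
seed: 11
output_dir: demo_run
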