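# Demo run: 2 tissues, 150 donors, 4 planted cis effects.
seed: 5
outdir: demo_run
n_donors: 150
donors_per_tissue: 130
n_variants: 100
n_genes: 25
n_tissues: 2
n_cis: 4
n_trans: 0
latent_k: 2
n_latent_truth: 1
perm_min: 200
perm_max: 1000
stages: [simulate, preprocess, cis, evaluate]
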