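# Demo pipeline configuration: a small synthetic cohort exercised end to end.
# Burden parameters are scaled up so the toy genome receives enough mutations
# for the signature and enrichment stages to be informative.
outdir: cmmosaic_demo
seed: 42
ref_length: 400000
n_genes: 8
n_signatures: 4
n_control_donors: 6
n_ihd_donors: 3
cells_per_donor: 3
beta0: 30000.0
beta1: 2000.0
beta_I: 80000.0
sigma_u: 5000.0
sigma_e: 10000.0
n_perm: 200
nmf_restarts: 10
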