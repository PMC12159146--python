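# Bundled demo: small synthetic cohort, all pipeline stages, < 2 minutes.
config_version: 1
seed: 7
n_patients: 11
samples_per_tissue_min: 4
samples_per_tissue_max: 8
n_proteins: 300
frac_stable_discriminative: 0.25
dsi_module_size: 40
dsi_omentum_shift: 1.0
dsi_hrd_shift: 0.75
stromal_omentum_shift: 1.0
intra_patient_sd: 0.3
inter_patient_sd: 1.0
missing_rate: 0.15
frac_hr_deficient: 0.36
qc_min_peptides: 500
qc_min_r: 0.8
min_tumor_pct: 20.0
cv_max: 0.25
beta: 7.0
min_module_size: 30
tau: 0.25
scar_rate_deficient: 3.0
scar_rate_intact: 1.0
cv_folds: 4
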