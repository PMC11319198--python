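# Sun-exposed (SE) skin preset.
# Ancestral-allele aberrant-splicing probability set to the published SE-skin
# Hom-ANC estimate (14.1%).  The SE expression fold change was not printed;
# the NSE value (2.2) is reused as the expression default.
name: se_skin
cohort:
  allele_frequency: 0.11
splice:
  p_aberrant_anc: 0.141
  p_aberrant_ins: 0.0
  allelic_expression_ratio: 2.2
  depth: 50
expression:
  beta0: 2.0
  afc_true: 2.2
  noise_sd_frac: 0.25
  n_covariates: 3
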