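# Not-sun-exposed (NSE) skin preset.
# Aberrant-splicing probability of the ancestral allele and the expression
# fold change of the insertion allele are set to the published NSE-skin
# cohort estimates (Hom-ANC aberrant fraction 15.6%; 2.2-fold expression).
name: nse_skin
cohort:
  allele_frequency: 0.11
splice:
  p_aberrant_anc: 0.156
  p_aberrant_ins: 0.0
  allelic_expression_ratio: 2.2
  depth: 50
expression:
  beta0: 2.0
  afc_true: 2.2
  noise_sd_frac: 0.25
  n_covariates: 3
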