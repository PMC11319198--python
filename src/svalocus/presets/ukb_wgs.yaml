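# UKB-style whole-genome sequencing preset for the DNA-evidence genotyper:
# 25x diploid coverage, 150 bp paired reads, 450 bp mean fragment, insertion
# allele frequency 11%, genotypes called with the UKB rule set.
name: ukb_wgs
cohort:
  allele_frequency: 0.11
dna:
  coverage: 25.0
  read_len: 150
  frag_mean: 450.0
  frag_sd: 100.0
  mapq0_prob: 0.8
rules: ukb
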