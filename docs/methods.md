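# Methods

This note records the models implemented in `svalocus`, the defaults and why
they were chosen, what the synthetic-data generators do and do not emulate,
and the numerical decisions a maintainer would otherwise have to reverse-
engineer from the code.

## Evidence model for a reference-present insertion

The inserted element is part of the reference assembly, so alignment
evidence is inverted relative to the usual insertion-calling setting:

* `n_INS` counts reads whose aligned span covers the element's **right
  breakpoint** with at least `min_breakpoint_anchor` aligned bases on each
  side. The permissive rule sets (1KGP, UKB) use a 1-bp anchor; the strict
  (GTEx-style) set requires 5 bp on each side and rejects any read with a
  soft-clip, because clipped breakpoint reads are the main false-positive
  mode in noisier alignments. The breakpoint base is defined as the last
  inserted base (interval end − 1); published coordinates mix the interval
  end and end − 1, a one-base ambiguity that no rule set is sensitive to.
* `n_ANC` counts discordant pairs with |TLEN| above `tlen_threshold`
  (default 2,500 bp against a 3,296-bp element). A pair is attributed to its
  leftmost mate so it is counted exactly once, and must satisfy a positional
  condition: by default both mate starts inside the element ± 1 kb flank
  window (which mate the published description meant is ambiguous; both-mates
  is the conservative reading and is configurable), or, under the strict
  set, one mate entirely before the left breakpoint and the other starting
  at or beyond the right breakpoint.

Duplicate, secondary, supplementary and QC-fail records are ignored. No
MAPQ floor is applied to DNA evidence: the element's low mappability makes
MAPQ-0 breakpoint reads genuinely informative.

Calling uses strict linear separators exactly as published:

| rule set | Hom-INS | Hom-ANC | otherwise |
|---|---|---|---|
| KGP  | n_INS > 3·n_ANC        | n_INS < 0.25·n_ANC      | Het |
| UKB  | n_INS > 10 + 3·n_ANC   | n_INS < 2 + 0.2·n_ANC   | Het |
| GTEX | n_ANC = 0 and n_INS ≥ 3 | n_INS < 3 and n_ANC > 0 | Het |

Ties on a separator (e.g. n_INS = 3·n_ANC) fall to Het because the printed
inequalities are strict. The strict set's conflicting corner (n_ANC = 0 and
n_INS < 3, i.e. no evidence of either allele) is NO_CALL.

## DNA read simulator

Each diploid is two haplotypes: the insertion haplotype is the reference
contig itself; the ancestral haplotype is the contig with the element's
interval deleted. Per haplotype, fragment count is Poisson with mean
`coverage/2 · hap_len / (2·read_len)`; fragment lengths are
Normal(`frag_mean`, `frag_sd`) truncated below at `2·read_len` (rounded);
starts are uniform. Defaults 25× / 150 bp / 450 ± 100 bp describe a
contemporary PCR-free short-read library.

Ancestral reads are mapped back to reference coordinates by shifting
post-deletion positions by the element length. A read that straddles the
deletion junction is reported the way a local aligner reports it: the larger
portion aligned, the smaller soft-clipped, with TLEN equal to the outer span
of the aligned portions. Consequences worth knowing:

* breakpoint-spanning reads can only arise from insertion haplotypes;
* a junction-spanning fragment produces an inflated-TLEN pair only when the
  junction falls more than `read_len/2` from both fragment ends (otherwise
  the straddling read is clipped to the far side and the pair's span
  collapses), so the expected long-TLEN pair count is
  `ρ · E[F − read_len]` for per-base fragment rate ρ — the closed form the
  test suite checks against;
* reads wholly inside the element (insertion haplotypes only) receive MAPQ 0
  with probability 0.8, a coarse stand-in for "low mappability throughout
  the element" which no source quantifies. Evidence counting does not use
  MAPQ, so this knob only matters for consumers that filter on it.

At the default 25× the UKB separators are not error-free: a heterozygote has
n_INS ≈ Poisson(12–13) against a Hom-ANC cut of 2 + 0.2·n_ANC ≈ 4.5, so
roughly 1% of heterozygotes fall below the cut and are called Hom-ANC,
bounding the true-vs-called dosage r² near 0.99 at these exact conditions
(the test suite measures this on 2,000-diploid cohorts). The real cohorts'
insert-size distributions and coverages are not published; the defaults here
are documented choices, not inferences, and higher coverage separates the
clusters essentially perfectly (also asserted in the tests at 40×).

## Splice-junction quantification

RNA alignments are filtered as in the GTEx pipeline: proper pair, vendor-QC
pass, edit distance (NM) ≤ 6, MAPQ exactly 255. Junctions come from CIGAR N
segments with ≥ 8 reference-aligned bases on both sides and intron length in
[50, 500000] — the regtools extraction parameters. Junctions are merged
across samples and kept only when the summed support exceeds 10 reads
(strictly), then per-sample counts are read off the retained set.

The aberrant-splicing fraction for a sample is
`n_ab / (n_ab + n_can)` where `n_ab` supports the exon-2 → SVA-F-acceptor
junction and `n_can` the canonical exon-2 → exon-3 junction; other exon-2
acceptors are deliberately excluded from the denominator. The cohort-level
("combined") fraction sums counts across samples before dividing, with a BCa
interval over resampled samples. The sQTL phenotype is
`ln((n_ab+1) / ((n_ab+1)+(n_can+1)))` — one pseudocount per junction count,
natural log (the base is a convention; association tests are invariant to
it) — defined only for samples with at least one exon-2 split read.

The splice-count generator draws a sample's total exon-2 split reads as
Poisson(`depth`, default 50) and its aberrant count as Binomial with
p = (w_anc·p_anc + w_ins·p_ins)/(w_anc + w_ins), where the allele weights
are dosage × allelic expression ratio. The presets couple the ratio to the
expression fold change (2.2), so a heterozygote's expected fraction is
p_anc/3.2 ≈ 0.049 when p_ins = 0 — the insertion allele both splices
normally and produces more transcript, diluting the aberrant share.

The poly(A) scanner counts terminal soft-clips of ≥ 5 bases with ≥ 90%
adenine (thymine for antisense reads) at each position of a window; both
thresholds are this package's choices — the observation they operationalize
("several reads ended in poly(A) sequences") was qualitative.

## Expression and allelic fold change

Per-sample TPM scaling factors are recovered from a highly expressed
reference gene as `counts / (effective length × TPM)`; effective length is
the length of the union of the gene's exons (a sum of exon lengths double-
counts overlapping exons). Region TPM = (count / region length) / factor.
Region read counting is split-aware: a read contributes when any aligned
block (CIGAR M/=/X run, with D bridged and N splitting) overlaps the region.

The eQTL is ordinary least squares `y = β₀ + β_g·g + X_cov·β_cov + ε`
(statsmodels); conditional analyses append the conditioning variant's dosage
as a covariate. aFC = 2β_g/β₀ + 1, computed as the ratio of alternate
(β₀ + 2β_g) to reference (β₀) allelic expression with each clamped below at
ε = 1e-6·max(|β₀|, 1); the published constraint is only "positive" and the
floor makes degenerate fits return a defined (tiny) value instead of
erroring. Confidence intervals use the bias-corrected and accelerated
bootstrap (scipy's BCa implementation, jackknife acceleration), resampling
donors jointly across y, g and covariates; a degenerate bootstrap
distribution yields a point interval with a warning.

The expression generator parameterizes the genotype effect through the fold
change, β_g = β₀(aFC − 1)/2, which makes noiseless recovery exact — an
identity the tests assert for arbitrary aFC and covariate structure. The
preset noise level (sd = 25% of β₀) gives a 500-donor cohort a replicate sd
of ~0.06 on the recovered aFC. Which real covariates matter is unknowable
here; three standard-normal covariates with geometrically decaying effects
stand in.

## Sibling QC

Pairs are flagged IBD2 when at most 3 of their SNP genotypes mismatch inside
a 2-Mb window centred on the locus; missing genotypes never count as
mismatches (conservative toward IBD2). Concordance across flagged pairs is
the share of identical calls, and accuracy is summarized as the squared
Pearson correlation of 0/1/2 dosages — the published accuracy number names
no estimator, and squared dosage correlation is this package's documented
interpretation, applied consistently. The generator gives IBD2 pairs
identical genotypes and non-IBD2 pairs Mendelian sibling sampling
conditioned on not sharing both parental haplotypes (otherwise the truth
flag would be wrong by construction); observation error replaces a genotype
with a uniform draw from {0,1,2}, so an error can silently coincide with the
truth — the enumeration oracle in the tests accounts for that.

## Haplotype statistics

EHH at variant j is the probability that two random core-allele carriers are
identical at every variant in the inclusive interval [focal, j], computed by
partition refinement as Σ C(n_h,2)/C(n_core,2); each side of the focal
variant is independent, the curve is defined at variant sites only (no
genetic-map interpolation) and truncated once it reaches 0. Bifurcation
trees refine the same partitions outward, with node sizes as line weights.
LD r² is the haplotype formula (p_AB − p_A·p_B)²/(p_A(1−p_A)p_B(1−p_B))
after a MAF > 1% filter and seeded uniform down-sampling without
replacement. Panels must be complete and phased; missing alleles are
rejected at construction.

The panel generator models a recent expansion as literal copying: derived-
allele carriers copy one core haplotype per site with probability
`sweep_strength` (else a background draw) and mutate at `mut_rate`;
ancestral carriers are independent background draws. It makes no attempt at
coalescent realism — no recombination map, no drift, no population
structure — so EHH decay rates are qualitative. sweep_strength 1 makes
derived EHH identically 1; sweep_strength 0 is the exchangeable null (the
tests check both, the latter by a KS test across replicate simulations).

## Pipeline and reproducibility

One flat YAML config with per-module blocks drives the demo; packaged
presets layer between defaults and user overrides. Validation collects every
violation before reporting. Stage seeds derive from the master seed as
`SeedSequence([seed, stage_index])` with a fixed stage table, so stages are
individually re-runnable; all outputs carry a provenance header (tool
version, seed, config hash with the output path excluded) and identical
config + seed reproduce identical bytes. Default problem sizes (120
genotyped samples, 30 sibling pairs, 500 expression donors, 300 splice
samples, 400 haplotypes; bootstrap 1,000 replicates in the demo versus
10,000 in one-off analyses) keep the full demo around a second while leaving
every statistic comfortably out of the small-count regime.

## Known limitations

* The miniature contig (~20 kb) preserves element lengths and spacing but
  not sequence content; there is no base-level error model, no real
  mappability landscape, and no split-read (supplementary-alignment)
  emission — straddling reads are soft-clipped primaries.
* Genotyping accuracy claims transfer to real cohorts only to the extent
  the insert-size distribution and coverage match the documented defaults;
  the separators themselves were calibrated upstream on real data.
* The splice model treats exon-2 split-read totals as Poisson and ignores
  overdispersion between donors.
* No genome-wide IBD detection, no iHS/XP-EHH cross-population statistics,
  no isoform-level expression deconvolution; allele-age inference and
  sequence-model (SpliceAI/APARENT-style) predictions are out of scope.
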