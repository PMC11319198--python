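# svalocus

Genotyping and functional analysis of a **reference-present SVA
retrotransposon insertion** from short-read sequencing evidence.

## The problem

A polymorphic ~3.3-kb SVA F1 retrotransposon sits in an early intron of
*ASIP* — and, unusually, the *inserted* allele is the one carried by the
GRCh38 reference. Standard read-depth SV callers fail here (the element has
very low mappability), but the two alleles leave complementary alignment
footprints:

* **insertion allele** — reads whose aligned bases continuously span the
  element's right breakpoint (`n_INS`);
* **ancestral allele** — discordant read pairs whose fragment lacks the
  element and therefore shows a template length (TLEN) inflated by ~3.3 kb
  (`n_ANC`).

`svalocus` implements the evidence counting, the three published
cohort-specific calling rule sets, and the downstream analyses that trace
the insertion's effects:

| stage | statistic |
|---|---|
| genotyping | `n_INS` vs `n_ANC` linear separators (1KGP / UKB / GTEx-strict rules) |
| QC | IBD2 sibling flagging (≤3 mismatches in a 2-Mb window) and cross-sibling call concordance / dosage r² |
| expression | linear eQTL `y = β₀ + β_g·g + X_cov·β_cov + ε`; allelic fold change `aFC = 2β_g/β₀ + 1` with BCa bootstrap CIs |
| splicing | split-read junction extraction (anchor ≥ 8, intron ∈ [50, 500000]); aberrant fraction `n_ab/(n_ab+n_can)` from the exon-2 donor; sQTL phenotype `ln((n_ab+1)/((n_ab+1)+(n_can+1)))`; poly(A) soft-clip scan |
| selection | extended haplotype homozygosity (EHH), haplotype bifurcation trees, LD r², per-population allele frequencies |

A first-class **synthetic-data module** emulates the locus — a ~20-kb
miniature contig preserving the real element lengths (1,612 and 3,296 bp)
and their 3,900-bp separation — so every stage runs end-to-end from a seed,
with no external downloads. Packaged presets (`nse_skin`, `se_skin`,
`ukb_wgs`) carry the published cohort calibrations (e.g. ancestral-allele
aberrant splicing probability 15.6% / 14.1%, expression fold change 2.2,
insertion allele frequency 11%).

## Worked example

Run the seeded end-to-end demonstration (simulate reads → genotype → sibling
QC → eQTL/aFC → splice fractions → EHH):

```bash
svalocus demo --seed 7 --out-dir demo_out
```

which prints (abridged):

```json
{
  "genotyping": {"n_samples": 120,
                 "call_counts": {"HOM_ANC": 92, "HET": 26, "HOM_INS": 2},
                 "dosage_r2_vs_truth": 1.0},
  "siblings":   {"n_pairs": 30, "n_ibd2_flagged": 11,
                 "fraction_concordant": 1.0, "dosage_r2": 1.0},
  "expression": {"afc": 2.1916, "ci": [2.068, 2.3521], "afc_true": 2.2},
  "splicing":   {"combined_fraction_by_dosage":
                   {"0": 0.156163, "1": 0.048108, "2": 0.0}},
  "haplotypes": {"ehh_derived_at_quarter": 0.091966,
                 "ehh_ancestral_at_quarter": 0.0}
}
```

Reading the numbers: the 120 simulated diploids cluster into the three
genotype classes and every call matches its true dosage (`dosage_r2 = 1.0`);
the 11 sibling pairs flagged IBD2 agree on every call; the eQTL fit recovers
the generating 2.2-fold expression increase with a bootstrap CI that covers
it; the combined aberrant-splicing fraction falls from 15.6% in
insertion-free samples to ~4.9% in heterozygotes and 0 in insertion
homozygotes (splicing into the old SVA F element is suppressed by the new
insertion); and the derived-allele haplotypes retain far higher homozygosity
away from the focal variant than ancestral ones — the classic signature of a
young, rapidly expanded allele.

Every output file carries a provenance header (tool version, seed, config
hash), and identical config + seed reproduce identical bytes.

Genotype your own alignments with

```bash
svalocus genotype --bam-list bams.txt \
    --locus chr20:34228122-34231419:34231418 --rules ukb --out geno
```

(the locus string is 0-based half-open with an optional breakpoint; the
example gives the GRCh38 coordinates of the real element).

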