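"""Seeded synthetic-data generators emulating a two-allele SVA insertion locus.

The generators build a miniature (~20 kb) analogue of an intron carrying two
SVA retrotransposons: an old, fixed SVA F element and, 3.9 kb downstream, a
young polymorphic SVA F1 insertion that is present in the reference
assembly.  Five generators produce the inputs the analysis stages consume:

* paired-end DNA reads over the locus, in insertion-present reference
  coordinates, where ancestral-allele fragments spanning the element show
  inflated template lengths and only insertion haplotypes yield
  breakpoint-spanning reads;
* canonical/aberrant splice-junction counts with a dosage-dependent
  expected aberrant share;
* expression with a configurable allelic fold change;
* phased haplotype panels in which derived-allele carriers descend from a
  single recent core haplotype;
* sibling genotype pairs with per-genotype observation error.

All generators are bit-reproducible for a fixed seed and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pysam
import yaml

from .genotyper import InsertionLocusSpec
from .haplotypes import HaplotypePanel

__all__ = [
    "LocusModel",
    "SimTruth",
    "SpliceSimConfig",
    "SimRead",
    "DEFAULT_LOCUS_CONFIG",
    "build_locus_model",
    "locus_spec_from_model",
    "simulate_dna_read_pairs",
    "simulate_dosages",
    "simulate_splice_counts",
    "simulate_expression",
    "simulate_haplotype_panel",
    "simulate_sibling_genotypes",
    "write_sam",
    "sam_header",
    "load_preset",
    "PRESET_NAMES",
]


class LocusConfigError(ValueError):
    """Raised for inconsistent locus geometry configuration."""


# Miniature stand-in for the real locus; the true GRCh38 element lengths
# (1,612 and 3,296 bp) and their 3,900 bp separation are preserved so the
# published rule sets apply unchanged.
DEFAULT_LOCUS_CONFIG: dict = {
    "contig_name": "miniASIP",
    "contig_length": 20_000,
    "sva_f_start": 3_000,
    "sva_f_length": 1_612,
    "sva_f1_gap": 3_900,
    "sva_f1_length": 3_296,
    "exon2_donor": 2_000,
    "exon3_acceptor": 14_000,
    "sva_acceptor": 3_600,
    "polya_site": 6_000,
}


@dataclass(frozen=True)
class LocusModel:
    """Geometry of the miniature two-SVA locus (0-based, half-open intervals)."""

    contig_name: str
    contig_length: int
    sva_f_interval: tuple[int, int]
    sva_f1_interval: tuple[int, int]
    right_breakpoint: int
    exon2_donor: int
    exon3_acceptor: int
    sva_acceptor: int
    polya_site: int

    def __post_init__(self) -> None:
        f_start, f_end = self.sva_f_interval
        f1_start, f1_end = self.sva_f1_interval
        coords = [f_start, f_end, f1_start, f1_end, self.right_breakpoint,
                  self.exon2_donor, self.exon3_acceptor, self.sva_acceptor, self.polya_site]
        if any(c < 0 or c >= self.contig_length for c in coords[:-1]) or not (
            0 <= self.polya_site < self.contig_length
        ):
            raise LocusConfigError("all coordinates must lie within [0, contig_length)")
        if not (f_start < f_end <= self.polya_site < f1_start < f1_end):
            raise LocusConfigError(
                "intervals must be disjoint and ordered sva_f < polya_site < sva_f1"
            )
        if not (f1_start <= self.right_breakpoint < f1_end):
            raise LocusConfigError("right_breakpoint must lie inside sva_f1_interval")
        if not (self.exon2_donor < self.exon3_acceptor):
            raise LocusConfigError("exon2_donor must precede exon3_acceptor")
        if not (self.exon2_donor < f_start):
            raise LocusConfigError("exon2_donor must precede the SVA F element")
        if not (f_start <= self.sva_acceptor < f_end):
            raise LocusConfigError("sva_acceptor must lie inside the SVA F element")
        if not (self.exon3_acceptor >= f1_end):
            raise LocusConfigError("exon3_acceptor must follow the SVA F1 element")

    @property
    def insertion_length(self) -> int:
        return self.sva_f1_interval[1] - self.sva_f1_interval[0]


def build_locus_model(config: Mapping | None = None) -> LocusModel:
    """Build a :class:`LocusModel` from a flat key-value config (defaults merged)."""
    cfg = dict(DEFAULT_LOCUS_CONFIG)
    if config:
        unknown = sorted(set(config) - set(cfg))
        if unknown:
            raise LocusConfigError(f"unknown locus config keys: {unknown}")
        cfg.update(config)
    for key in ("contig_length", "sva_f_length", "sva_f1_gap", "sva_f1_length"):
        if cfg[key] <= 0:
            raise LocusConfigError(f"{key} must be positive")
    f_start = int(cfg["sva_f_start"])
    f_end = f_start + int(cfg["sva_f_length"])
    f1_start = f_end + int(cfg["sva_f1_gap"])
    f1_end = f1_start + int(cfg["sva_f1_length"])
    return LocusModel(
        contig_name=str(cfg["contig_name"]),
        contig_length=int(cfg["contig_length"]),
        sva_f_interval=(f_start, f_end),
        sva_f1_interval=(f1_start, f1_end),
        right_breakpoint=f1_end - 1,  # last inserted base
        exon2_donor=int(cfg["exon2_donor"]),
        exon3_acceptor=int(cfg["exon3_acceptor"]),
        sva_acceptor=int(cfg["sva_acceptor"]),
        polya_site=int(cfg["polya_site"]),
    )


def locus_spec_from_model(model: LocusModel) -> InsertionLocusSpec:
    """Genotyper locus spec matching the simulated SVA F1 element."""
    return InsertionLocusSpec(
        contig=model.contig_name,
        ins_start=model.sva_f1_interval[0],
        ins_end=model.sva_f1_interval[1],
        right_breakpoint=model.right_breakpoint,
    )


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth genotype for one simulated sample."""

    sample_id: str
    genotype_dosage: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genotype_dosage not in (0, 1, 2):
            raise ValueError("genotype_dosage must be 0, 1 or 2")


@dataclass(frozen=True)
class SpliceSimConfig:
    """Per-allele aberrant-splicing probabilities and sequencing depth."""

    p_aberrant_anc: float
    p_aberrant_ins: float = 0.0
    allelic_expression_ratio: float = 1.0
    depth: float = 50.0

    def __post_init__(self) -> None:
        for p in (self.p_aberrant_anc, self.p_aberrant_ins):
            if not 0.0 <= p <= 1.0:
                raise ValueError("aberrant probabilities must lie in [0, 1]")
        if self.depth <= 0 or self.allelic_expression_ratio <= 0:
            raise ValueError("depth and allelic_expression_ratio must be positive")

    def expected_fraction(self, dosage: int) -> float:
        """Dosage-weighted expected aberrant share across the two alleles."""
        w_ins = dosage * self.allelic_expression_ratio
        w_anc = (2 - dosage) * 1.0
        return (w_anc * self.p_aberrant_anc + w_ins * self.p_aberrant_ins) / (w_anc + w_ins)


@dataclass
class SimRead:
    """Lightweight alignment record sharing pysam's attribute surface.

    The genotyper consumes these directly; :func:`write_sam` serializes them
    losslessly to SAM for round-tripping through pysam.
    """

    query_name: str
    reference_name: str
    reference_start: int
    cigartuples: tuple[tuple[int, int], ...]
    mapping_quality: int
    template_length: int
    next_reference_start: int
    is_reverse: bool
    is_read1: bool
    is_proper_pair: bool = True
    is_paired: bool = True
    is_unmapped: bool = False
    is_duplicate: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    is_qcfail: bool = False
    mate_is_unmapped: bool = False
    mate_is_reverse: bool = False
    query_sequence: str | None = None
    tags: dict = field(default_factory=dict)

    @property
    def is_read2(self) -> bool:
        return not self.is_read1

    @property
    def reference_end(self) -> int:
        end = self.reference_start
        for op, length in self.cigartuples:
            if op in (0, 2, 3, 7, 8):  # reference-consuming ops
                end += length
        return end

    def get_tag(self, name: str):
        return self.tags[name]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _truncated_normal(rng, mean, sd, lower, size):
    """Normal(mean, sd) truncated below at ``lower`` by resampling."""
    out = rng.normal(mean, sd, size)
    bad = out < lower
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < lower
    return out


def simulate_dna_read_pairs(
    truth: SimTruth,
    model: LocusModel,
    coverage: float = 25.0,
    read_len: int = 150,
    frag_mean: float = 450.0,
    frag_sd: float = 100.0,
    mapq0_prob: float = 0.8,
    seed=None,
) -> list[SimRead]:
    """Simulate paired-end DNA reads for one diploid over the miniature locus.

    Reads are reported in insertion-present reference coordinates.  The
    insertion haplotype is the reference itself; the ancestral haplotype
    lacks the SVA F1 interval, so its coordinates past the deletion point
    shift by the element length, inflating the template length of fragments
    that span it.  An ancestral read that straddles the deletion junction is
    reported the way a local aligner would report it: the larger portion
    aligned, the remainder soft-clipped (such reads never span the right
    breakpoint).  Reads wholly inside the element (insertion haplotype only)
    are assigned mapping quality 0 with probability ``mapq0_prob``, modelling
    the element's low mappability.
    """
    if model.contig_length <= 0:
        raise ValueError("zero-length contig")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if frag_mean <= 2 * read_len:
        raise ValueError("frag_mean must exceed 2*read_len")
    rng = _rng(seed if seed is not None else truth.seed)
    ins_start, ins_end = model.sva_f1_interval
    ins_len = model.insertion_length
    reads: list[SimRead] = []

    def place(hap_start: int, hap_end: int, has_ins: bool) -> tuple[int, tuple, int]:
        """Map a read's haplotype interval to (ref_start, cigar, ref_end)."""
        length = hap_end - hap_start
        if has_ins:
            return hap_start, ((0, length),), hap_end
        if hap_end <= ins_start:
            return hap_start, ((0, length),), hap_end
        if hap_start >= ins_start:
            return hap_start + ins_len, ((0, length),), hap_end + ins_len
        left = ins_start - hap_start
        right = length - left
        if left >= right:  # align the left portion, clip the rest
            return hap_start, ((0, left), (4, right)), ins_start
        return ins_end, ((4, left), (0, right)), ins_end + right

    haplotypes = [True] * truth.genotype_dosage + [False] * (2 - truth.genotype_dosage)
    for hap_idx, has_ins in enumerate(haplotypes):
        hap_len = model.contig_length if has_ins else model.contig_length - ins_len
        n_frag = rng.poisson((coverage / 2.0) * hap_len / (2.0 * read_len))
        frag_lens = np.rint(
            _truncated_normal(rng, frag_mean, frag_sd, 2 * read_len, n_frag)
        ).astype(int)
        frag_lens = np.minimum(frag_lens, hap_len)
        starts = np.floor(rng.random(n_frag) * (hap_len - frag_lens + 1)).astype(int)
        mapq_draw = rng.random(n_frag * 2)
        for k in range(n_frag):
            s, flen = int(starts[k]), int(frag_lens[k])
            r1 = place(s, s + read_len, has_ins)
            r2 = place(s + flen - read_len, s + flen, has_ins)
            span_start = min(r1[0], r2[0])
            span_end = max(r1[2], r2[2])
            tlen = span_end - span_start
            proper = tlen <= frag_mean + 4 * frag_sd
            for ridx, (mine, mate) in enumerate(((r1, r2), (r2, r1))):
                ref_start, cigar, ref_end = mine
                mapq = 60
                if has_ins and ref_start >= ins_start and ref_end <= ins_end:
                    if mapq_draw[2 * k + ridx] < mapq0_prob:
                        mapq = 0
                reads.append(
                    SimRead(
                        query_name=f"{truth.sample_id}:{hap_idx}:{k}",
                        reference_name=model.contig_name,
                        reference_start=ref_start,
                        cigartuples=cigar,
                        mapping_quality=mapq,
                        template_length=tlen if ref_start == span_start else -tlen,
                        next_reference_start=mate[0],
                        is_reverse=ridx == 1,
                        mate_is_reverse=ridx == 0,
                        is_read1=ridx == 0,
                        is_proper_pair=proper,
                    )
                )
    reads.sort(key=lambda r: (r.reference_start, r.query_name, not r.is_read1))
    return reads


def simulate_dosages(n: int, allele_frequency: float, seed=None) -> np.ndarray:
    """Hardy-Weinberg insertion dosages for ``n`` diploids."""
    if not 0.0 < allele_frequency < 1.0:
        raise ValueError("allele_frequency must lie in (0, 1)")
    rng = _rng(seed)
    return rng.binomial(2, allele_frequency, size=n)


def simulate_splice_counts(
    truth: SimTruth, cfg: SpliceSimConfig, seed=None
) -> tuple[int, int]:
    """(n_canonical, n_aberrant) exon-2 split-read counts for one sample.

    The total exon-2 split-read count is Poisson(depth); the aberrant count
    is binomial with the dosage-weighted expected share
    f = (w_anc*p_anc + w_ins*p_ins)/(w_anc + w_ins), where the insertion
    allele's expression weight is scaled by ``allelic_expression_ratio``.
    """
    rng = _rng(seed if seed is not None else truth.seed)
    f = cfg.expected_fraction(truth.genotype_dosage)
    total = int(rng.poisson(cfg.depth))
    n_aberrant = int(rng.binomial(total, f)) if total > 0 else 0
    return total - n_aberrant, n_aberrant


def simulate_expression(
    truths: Sequence[SimTruth],
    beta0: float,
    afc_true: float,
    covariates: np.ndarray | None = None,
    cov_effects: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed=None,
) -> np.ndarray:
    """Expression vector y = beta0 + beta_g*g + X@b + Normal(0, noise_sd).

    The genotype effect is parameterized through the allelic fold change:
    beta_g = beta0*(afc_true - 1)/2, so the generating fold change is
    exactly recoverable from a noiseless fit.
    """
    if afc_true <= 0 or beta0 <= 0:
        raise ValueError("afc_true and beta0 must be positive")
    rng = _rng(seed)
    g = np.array([t.genotype_dosage for t in truths], dtype=float)
    beta_g = beta0 * (afc_true - 1.0) / 2.0
    y = beta0 + beta_g * g
    if covariates is not None and np.size(covariates) > 0:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] != g.size:
            X = X.T
        effects = np.asarray(cov_effects, dtype=float).ravel()
        if X.shape != (g.size, effects.size):
            raise ValueError("covariate matrix and effect vector dimensions disagree")
        y = y + X @ effects
    elif cov_effects is not None and np.size(cov_effects) > 0:
        raise ValueError("cov_effects given without covariates")
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, g.size)
    return y


def simulate_haplotype_panel(
    n_hap: int,
    n_var: int,
    focal_freq: float,
    sweep_strength: float,
    mut_rate: float = 0.0,
    seed=None,
    position_spacing: int = 250,
) -> HaplotypePanel:
    """Phased 0/1 panel with a recently expanded core haplotype.

    Derived-allele carriers at the focal variant (column ``n_var // 2``) are
    per-site copies of one core haplotype with copying fidelity
    ``sweep_strength`` (1 = perfect copies, 0 = background draws), followed
    by independent flips at ``mut_rate``; ancestral-allele haplotypes are
    independent draws from per-site background frequencies.  The derived
    count is round(focal_freq * n_hap).
    """
    if not 0.0 < focal_freq < 1.0:
        raise ValueError("focal_freq must lie in (0, 1)")
    if n_hap < 4:
        raise ValueError("need at least 4 haplotypes")
    if not 0.0 <= sweep_strength <= 1.0:
        raise ValueError("sweep_strength must lie in [0, 1]")
    rng = _rng(seed)
    n_derived = int(np.rint(focal_freq * n_hap))
    n_derived = min(max(n_derived, 2), n_hap - 2)
    q = rng.uniform(0.05, 0.95, size=n_var)
    core = (rng.random(n_var) < q).astype(np.int8)
    derived = np.where(
        rng.random((n_derived, n_var)) < sweep_strength,
        core[None, :],
        (rng.random((n_derived, n_var)) < q).astype(np.int8),
    ).astype(np.int8)
    if mut_rate > 0:
        flips = rng.random((n_derived, n_var)) < mut_rate
        derived = np.where(flips, 1 - derived, derived)
    ancestral = (rng.random((n_hap - n_derived, n_var)) < q).astype(np.int8)
    alleles = np.vstack([derived, ancestral])
    focal = n_var // 2
    alleles[:n_derived, focal] = 1
    alleles[n_derived:, focal] = 0
    positions = 1000 + position_spacing * np.arange(n_var, dtype=np.int64)
    return HaplotypePanel(alleles=alleles, positions=positions, focal_index=focal)


@dataclass(frozen=True)
class SibPairSim:
    """Paired sibling genotype matrices with IBD2 truth flags."""

    geno_a: np.ndarray
    geno_b: np.ndarray
    ibd2: np.ndarray
    positions: np.ndarray
    center: int
    window: int


def simulate_sibling_genotypes(
    n_pairs: int,
    n_var: int,
    err_rate: float,
    ibd2_fraction: float,
    seed=None,
    center: int = 1_500_000,
    window: int = 2_000_000,
) -> SibPairSim:
    """Sibling genotype pairs over a local SNP window, with observation error.

    IBD2 pairs share identical underlying genotypes; non-IBD2 pairs are
    built by Mendelian sampling from two simulated parents (each sibling
    draws one haplotype per parent), conditioned on the siblings not
    inheriting the same haplotype from both parents (otherwise the pair
    would be IBD2 despite its truth flag).  Observation error
    replaces a genotype, with probability ``err_rate``, by a uniform draw
    from {0, 1, 2} (which may coincide with the truth).
    """
    if not (0.0 <= err_rate <= 1.0 and 0.0 <= ibd2_fraction <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    rng = _rng(seed)
    p = rng.uniform(0.1, 0.9, size=n_var)
    ibd2 = rng.random(n_pairs) < ibd2_fraction
    geno_a = np.empty((n_pairs, n_var), dtype=np.int8)
    geno_b = np.empty((n_pairs, n_var), dtype=np.int8)
    for i in range(n_pairs):
        if ibd2[i]:
            g = (rng.random(n_var) < p).astype(np.int8) + (rng.random(n_var) < p).astype(np.int8)
            geno_a[i] = g
            geno_b[i] = g
        else:
            mother = (rng.random((2, n_var)) < p).astype(np.int8)
            father = (rng.random((2, n_var)) < p).astype(np.int8)
            a_m, a_f = rng.integers(0, 2, size=2)
            while True:
                b_m, b_f = rng.integers(0, 2, size=2)
                if (b_m, b_f) != (a_m, a_f):
                    break
            geno_a[i] = mother[a_m] + father[a_f]
            geno_b[i] = mother[b_m] + father[b_f]

    def observe(g: np.ndarray) -> np.ndarray:
        if err_rate == 0:
            return g.copy()
        mask = rng.random(g.shape) < err_rate
        noise = rng.integers(0, 3, size=g.shape).astype(np.int8)
        return np.where(mask, noise, g)

    obs_a = observe(geno_a)
    obs_b = observe(geno_b)
    half = window // 2
    positions = (
        center - half + ((np.arange(n_var) + 0.5) * window / n_var).astype(np.int64)
    )
    return SibPairSim(
        geno_a=obs_a, geno_b=obs_b, ibd2=ibd2, positions=positions,
        center=center, window=window,
    )


# ---------------------------------------------------------------------------
# SAM serialization


def sam_header(model: LocusModel) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": model.contig_name, "LN": model.contig_length}],
        }
    )


def to_pysam(read: SimRead, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = read.query_name
    seg.reference_id = 0
    seg.reference_start = read.reference_start
    seg.cigartuples = list(read.cigartuples)
    seg.mapping_quality = read.mapping_quality
    seg.template_length = read.template_length
    seg.next_reference_id = 0
    seg.next_reference_start = read.next_reference_start
    if read.query_sequence is not None:
        seg.query_sequence = read.query_sequence
    flag = 0x1 if read.is_paired else 0
    if read.is_proper_pair:
        flag |= 0x2
    if read.is_unmapped:
        flag |= 0x4
    if read.mate_is_unmapped:
        flag |= 0x8
    if read.is_reverse:
        flag |= 0x10
    if read.mate_is_reverse:
        flag |= 0x20
    if read.is_read1:
        flag |= 0x40
    else:
        flag |= 0x80
    if read.is_secondary:
        flag |= 0x100
    if read.is_qcfail:
        flag |= 0x200
    if read.is_duplicate:
        flag |= 0x400
    if read.is_supplementary:
        flag |= 0x800
    seg.flag = flag
    for tag, value in read.tags.items():
        seg.set_tag(tag, value)
    return seg


def write_sam(reads: Sequence[SimRead], model: LocusModel, path) -> None:
    """Serialize simulated reads as coordinate-sorted SAM with an @SQ header."""
    header = sam_header(model)
    ordered = sorted(reads, key=lambda r: (r.reference_start, r.query_name, not r.is_read1))
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for read in ordered:
            out.write(to_pysam(read, header))


# ---------------------------------------------------------------------------
# Packaged presets

PRESET_NAMES = ("nse_skin", "se_skin", "ukb_wgs")


def load_preset(name: str) -> dict:
    """Load a packaged preset configuration by name."""
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
    text = resources.files("svalocus.presets").joinpath(f"{name}.yaml").read_text()
    return yaml.safe_load(text)


def splice_config_from_preset(preset: dict) -> SpliceSimConfig:
    sp = preset["splice"]
    return SpliceSimConfig(
        p_aberrant_anc=float(sp["p_aberrant_anc"]),
        p_aberrant_ins=float(sp["p_aberrant_ins"]),
        allelic_expression_ratio=float(sp["allelic_expression_ratio"]),
        depth=float(sp["depth"]),
    )
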