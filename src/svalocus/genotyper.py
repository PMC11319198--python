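"""Genotyping a reference-present insertion from short-read alignment evidence.

The insertion allele is the one carried by the reference assembly, so the
two alleles leave complementary footprints in read alignments:

* insertion allele: reads whose aligned bases continuously span the right
  breakpoint of the inserted element (n_INS);
* ancestral (non-insertion) allele: discordant read pairs whose fragment
  lacks the inserted sequence and therefore shows an inflated template
  length (TLEN) across the element (n_ANC).

Three published rule sets turn the (n_INS, n_ANC) evidence pair into a
genotype call; they differ in their linear separators and, for the strict
variant, in how evidence reads are defined (minimum 5 bp anchors, no
soft-clipping, mates strictly bracketing the element).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "Evidence",
    "Call",
    "InsertionLocusSpec",
    "RuleSet",
    "InsertionEvidence",
    "GenotypeCall",
    "classify_alignment_evidence",
    "count_evidence",
    "call_genotype",
    "genotype_cohort",
    "write_genotype_vcf",
]


class Evidence(enum.Enum):
    INS_SUPPORT = "INS_SUPPORT"
    ANC_SUPPORT = "ANC_SUPPORT"
    UNINFORMATIVE = "UNINFORMATIVE"


class Call(enum.Enum):
    HOM_ANC = "HOM_ANC"
    HET = "HET"
    HOM_INS = "HOM_INS"
    NO_CALL = "NO_CALL"


_DOSAGE = {Call.HOM_ANC: 0, Call.HET: 1, Call.HOM_INS: 2}


@dataclass(frozen=True)
class InsertionLocusSpec:
    """Coordinates of a reference-present insertion (0-based, half-open).

    ``right_breakpoint`` is the last inserted base; breakpoint-spanning
    reads must cover it with aligned bases on both sides.  ``flank_window``
    bounds where discordant-pair mates may start; ``tlen_threshold`` is the
    minimum |TLEN| marking a pair as spanning the missing element.
    """

    contig: str
    ins_start: int
    ins_end: int
    right_breakpoint: int | None = None
    flank_window: int = 1000
    tlen_threshold: int = 2500

    def __post_init__(self) -> None:
        if self.right_breakpoint is None:
            object.__setattr__(self, "right_breakpoint", self.ins_end - 1)
        if not (self.ins_start < self.right_breakpoint <= self.ins_end):
            raise ValueError("require ins_start < right_breakpoint <= ins_end")
        if self.flank_window <= 0 or self.tlen_threshold <= 0:
            raise ValueError("flank_window and tlen_threshold must be positive")

    @property
    def insertion_length(self) -> int:
        return self.ins_end - self.ins_start


@dataclass(frozen=True)
class RuleSet:
    """One cohort's genotype-calling rules.

    HOM_INS iff n_ins > homins_intercept + homins_slope * n_anc and
    HOM_ANC iff n_ins < homanc_intercept + homanc_slope * n_anc, with the
    strict inequalities as published; everything else is HET.  The strict
    (GTEx-style) rule set replaces the separators with count thresholds:
    HOM_INS iff n_anc = 0 and n_ins >= min_ins_reads, HOM_ANC iff
    n_ins < min_ins_reads and n_anc > 0, NO_CALL when both evidence classes
    are effectively absent.
    """

    name: str
    homins_intercept: float
    homins_slope: float
    homanc_intercept: float
    homanc_slope: float
    strict_evidence: bool = False
    min_breakpoint_anchor: int = 1
    forbid_softclip: bool = False
    min_ins_reads: int = 3

    def __post_init__(self) -> None:
        if not self.homins_slope > self.homanc_slope >= 0:
            raise ValueError("require homins_slope > homanc_slope >= 0")

    @classmethod
    def kgp(cls) -> "RuleSet":
        return cls("KGP", 0.0, 3.0, 0.0, 0.25)

    @classmethod
    def ukb(cls) -> "RuleSet":
        return cls("UKB", 10.0, 3.0, 2.0, 0.2)

    @classmethod
    def gtex(cls) -> "RuleSet":
        return cls(
            "GTEX", 0.0, 3.0, 0.0, 0.25,
            strict_evidence=True, min_breakpoint_anchor=5, forbid_softclip=True,
        )

    @classmethod
    def by_name(cls, name: str) -> "RuleSet":
        try:
            return {"kgp": cls.kgp, "ukb": cls.ukb, "gtex": cls.gtex}[name.lower()]()
        except KeyError:
            raise ValueError(f"unknown rule set {name!r}; choose kgp, ukb or gtex") from None


@dataclass(frozen=True)
class InsertionEvidence:
    sample_id: str
    n_ins: int
    n_anc: int

    def __post_init__(self) -> None:
        if self.n_ins < 0 or self.n_anc < 0:
            raise ValueError("evidence counts must be non-negative")


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    call: Call
    dosage: int | None
    rule_set: str

    def __post_init__(self) -> None:
        if self.call is Call.NO_CALL:
            if self.dosage is not None:
                raise ValueError("NO_CALL must have missing dosage")
        elif self.dosage != _DOSAGE[self.call]:
            raise ValueError(f"dosage {self.dosage} inconsistent with {self.call}")


def _has_softclip(rec) -> bool:
    return any(op in (4, 5) for op, _ in (rec.cigartuples or []))


def classify_alignment_evidence(
    rec, locus: InsertionLocusSpec, rules: RuleSet
) -> Evidence:
    """Classify one alignment record as INS/ANC support or uninformative.

    INS_SUPPORT: the aligned span covers the right breakpoint with at least
    ``rules.min_breakpoint_anchor`` aligned bases on each side (and no
    soft-clipping when the rule set forbids it).  ANC_SUPPORT: the pair is
    discordantly long (|TLEN| > threshold) and positioned per the rule set
    (default: both mate starts inside the flank window; strict: the mates
    bracket the inserted element).  A pair is counted once, at its leftmost
    mate.  Unmapped, duplicate, secondary/supplementary and QC-fail records
    are uninformative, never errors.
    """
    if (
        rec.is_unmapped
        or rec.is_duplicate
        or rec.is_secondary
        or rec.is_supplementary
        or rec.is_qcfail
    ):
        return Evidence.UNINFORMATIVE
    if rec.reference_name != locus.contig:
        raise ValueError(
            f"record aligned to {rec.reference_name!r} but locus is on {locus.contig!r}"
        )

    rb = locus.right_breakpoint
    a = rules.min_breakpoint_anchor
    start, end = rec.reference_start, rec.reference_end
    if start is not None and end is not None and start <= rb - a and end - 1 >= rb + a:
        if not (rules.forbid_softclip and _has_softclip(rec)):
            return Evidence.INS_SUPPORT

    # Discordant-pair (ancestral allele) evidence, counted at the leftmost mate.
    if not rec.is_paired or rec.mate_is_unmapped:
        return Evidence.UNINFORMATIVE
    mate_start = rec.next_reference_start
    if mate_start is None or mate_start < 0:
        return Evidence.UNINFORMATIVE
    leftmost = start < mate_start or (start == mate_start and rec.is_read1)
    if not leftmost:
        return Evidence.UNINFORMATIVE
    if abs(rec.template_length) <= locus.tlen_threshold:
        return Evidence.UNINFORMATIVE
    if rules.strict_evidence:
        # one read before the left breakpoint, the mate at/after the right one
        if start < locus.ins_start and mate_start >= locus.ins_end:
            return Evidence.ANC_SUPPORT
        return Evidence.UNINFORMATIVE
    lo = locus.ins_start - locus.flank_window
    hi = locus.ins_end + locus.flank_window
    if lo <= start < hi and lo <= mate_start < hi:
        return Evidence.ANC_SUPPORT
    return Evidence.UNINFORMATIVE


def count_evidence(
    records: Iterable, locus: InsertionLocusSpec, rules: RuleSet, sample_id: str
) -> InsertionEvidence:
    """Tally INS-supporting reads and ANC-supporting pairs over a record stream.

    The result is order-independent: each record is classified in isolation
    (pairs are attributed to their leftmost mate), so shuffling or chunking
    the stream cannot change the counts.
    """
    n_ins = 0
    n_anc = 0
    for rec in records:
        ev = classify_alignment_evidence(rec, locus, rules)
        if ev is Evidence.INS_SUPPORT:
            n_ins += 1
        elif ev is Evidence.ANC_SUPPORT:
            n_anc += 1
    return InsertionEvidence(sample_id=sample_id, n_ins=n_ins, n_anc=n_anc)


def call_genotype(ev: InsertionEvidence, rules: RuleSet) -> GenotypeCall:
    """Apply a rule set's separators to one sample's evidence counts."""
    n_ins, n_anc = ev.n_ins, ev.n_anc
    if rules.strict_evidence:
        if n_anc == 0 and n_ins >= rules.min_ins_reads:
            call = Call.HOM_INS
        elif n_ins < rules.min_ins_reads and n_anc > 0:
            call = Call.HOM_ANC
        elif n_ins < rules.min_ins_reads and n_anc == 0:
            call = Call.NO_CALL
        else:
            call = Call.HET
    else:
        if n_ins > rules.homins_intercept + rules.homins_slope * n_anc:
            call = Call.HOM_INS
        elif n_ins < rules.homanc_intercept + rules.homanc_slope * n_anc:
            call = Call.HOM_ANC
        else:
            call = Call.HET
    dosage = _DOSAGE.get(call)
    return GenotypeCall(sample_id=ev.sample_id, call=call, dosage=dosage, rule_set=rules.name)


def _iter_alignment_file(path, contig: str, start: int, end: int):
    mode = "r" if str(path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(path), mode) as af:
        if af.has_index():
            yield from af.fetch(contig, start, end)
        else:
            for rec in af:
                if rec.reference_name == contig:
                    yield rec


def genotype_cohort(
    bam_paths: Sequence,
    locus: InsertionLocusSpec,
    rules: RuleSet,
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Genotype every sample; returns the evidence/call table for cluster plots.

    Columns: sample_id, n_ins, n_anc, call, dosage.  An unreadable file
    yields a per-sample NO_CALL with a logged warning; only if every file
    fails is an error raised.
    """
    if sample_ids is None:
        sample_ids = [f"S{k}" for k in range(len(bam_paths))]
    if len(sample_ids) != len(bam_paths):
        raise ValueError("sample_ids must match bam_paths in length")
    rows = []
    n_failed = 0
    fetch_lo = max(0, locus.ins_start - locus.flank_window - locus.tlen_threshold)
    fetch_hi = locus.ins_end + locus.flank_window + locus.tlen_threshold
    for sample, path in zip(sample_ids, bam_paths):
        try:
            records = _iter_alignment_file(path, locus.contig, fetch_lo, fetch_hi)
            ev = count_evidence(records, locus, rules, sample)
            gc = call_genotype(ev, rules)
            rows.append((sample, ev.n_ins, ev.n_anc, gc.call.value, gc.dosage))
        except (OSError, ValueError) as exc:
            n_failed += 1
            logger.warning("could not genotype %s (%s): %s", sample, path, exc)
            rows.append((sample, 0, 0, Call.NO_CALL.value, None))
    if bam_paths and n_failed == len(bam_paths):
        raise RuntimeError("all alignment files failed to genotype")
    df = pd.DataFrame(rows, columns=["sample_id", "n_ins", "n_anc", "call", "dosage"])
    df["dosage"] = df["dosage"].astype("Float64")
    return df


def calls_from_evidence(
    evidence: Iterable[InsertionEvidence], rules: RuleSet
) -> pd.DataFrame:
    """Call genotypes for precomputed evidence counts (same table layout)."""
    rows = []
    for ev in evidence:
        gc = call_genotype(ev, rules)
        rows.append((ev.sample_id, ev.n_ins, ev.n_anc, gc.call.value, gc.dosage))
    df = pd.DataFrame(rows, columns=["sample_id", "n_ins", "n_anc", "call", "dosage"])
    df["dosage"] = df["dosage"].astype("Float64")
    return df


def write_genotype_vcf(
    calls: pd.DataFrame, locus: InsertionLocusSpec, path, contig_length: int | None = None
) -> None:
    """Write one symbolic VCF 4.2 record carrying per-sample genotypes.

    The inserted element is present in the reference, so the ALT allele is
    a symbolic deletion of it (<DEL:ME:SVA>); an insertion dosage of d
    corresponds to 2-d ALT copies (Hom-INS = 0/0, Hom-ANC = 1/1).  The
    convention is documented in the header.
    """
    header = pysam.VariantHeader()
    header.add_line("##source=svalocus")
    length = contig_length if contig_length is not None else locus.ins_end + 10_000
    header.contigs.add(locus.contig, length=length)
    header.add_line('##ALT=<ID=DEL:ME:SVA,Description="Deletion of reference-present SVA element">')
    header.add_line(
        "##META=<Description=\"The insertion allele is the REF (reference-present) allele; "
        "ALT models the ancestral allele lacking the element. Insertion dosage = 2 - ALT dosage.\">"
    )
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End of the deleted element">')
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for sample in calls["sample_id"]:
        header.add_sample(str(sample))
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        if len(calls):
            rec = vf.new_record(
                contig=locus.contig,
                start=locus.ins_start,
                stop=locus.ins_end,
                alleles=("N", "<DEL:ME:SVA>"),
                id="SVA_INS",
            )
            rec.info["SVTYPE"] = "DEL"
            rec.info["SVLEN"] = -locus.insertion_length
            for sample, dosage in zip(calls["sample_id"], calls["dosage"]):
                if pd.isna(dosage):
                    rec.samples[str(sample)]["GT"] = (None, None)
                else:
                    n_alt = 2 - int(dosage)
                    rec.samples[str(sample)]["GT"] = tuple(
                        sorted([1] * n_alt + [0] * (2 - n_alt))
                    )
            vf.write(rec)


def scaled_ruleset(rules: RuleSet, **overrides) -> RuleSet:
    """Convenience for configurable variants of a published rule set."""
    return replace(rules, **overrides)
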