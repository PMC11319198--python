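"""Splice-junction quantification from split-read alignments.

Junctions are extracted from CIGAR N segments with regtools-style filters
(minimum anchor 8 bp on both sides, intron length within [50, 500000]),
merged across samples to retain non-spurious junctions (total count > 10),
and summarized as the aberrant-splicing fraction: of all split reads leaving
the exon-2 donor, the share that splices into the cryptic acceptor inside
the upstream SVA F element rather than to the canonical exon-3 acceptor.
The sQTL phenotype is the pseudocounted log-fraction of aberrant junction
reads.  A small scanner counts adenine-rich terminal soft-clips as direct
evidence of premature polyadenylation of the aberrant transcript.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import RnaFilterSpec, bca_interval

__all__ = [
    "JunctionCount",
    "SpliceFraction",
    "filter_rna_alignment",
    "extract_junctions",
    "merge_filter_junctions",
    "aberrant_splice_fraction",
    "combined_splice_fraction",
    "sqtl_phenotype",
    "detect_polya_softclips",
    "write_junction_bed",
    "read_junction_bed",
]

MIN_ANCHOR = 8
MIN_INTRON = 50
MAX_INTRON = 500_000

_DEFAULT_FILTER = RnaFilterSpec()


@dataclass(frozen=True, order=True)
class JunctionCount:
    """A splice junction keyed by its intron interval (0-based, half-open)."""

    contig: str
    intron_start: int
    intron_end: int
    strand: str = "?"
    n_reads: int = 0

    def __post_init__(self) -> None:
        if self.intron_end <= self.intron_start:
            raise ValueError("intron_end must exceed intron_start")
        if self.strand not in ("+", "-", "?"):
            raise ValueError("strand must be '+', '-' or '?'")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.contig, self.intron_start, self.intron_end, self.strand)


def filter_rna_alignment(rec, filters: RnaFilterSpec = _DEFAULT_FILTER) -> bool:
    """True iff the record passes the RNA-seq alignment filters."""
    try:
        return filters.keep(rec)
    except Exception:
        return False


def extract_junctions(
    records: Iterable,
    min_anchor: int = MIN_ANCHOR,
    min_intron: int = MIN_INTRON,
    max_intron: int = MAX_INTRON,
) -> list[JunctionCount]:
    """Count splice junctions supported by CIGAR N segments.

    Each N segment whose flanking aligned stretches are both >= ``min_anchor``
    reference bases, and whose length lies in [min_intron, max_intron],
    increments its junction's count.  Strand comes from the XS tag when
    present, else '?'.  Records are assumed pre-filtered; malformed CIGARs
    are skipped with a counted warning.
    """
    counts: dict[tuple[str, int, int, str], int] = {}
    n_bad = 0
    for rec in records:
        cig = rec.cigartuples
        if not cig:
            n_bad += 1
            continue
        try:
            strand = rec.get_tag("XS")
        except (KeyError, AttributeError):
            strand = "?"
        if strand not in ("+", "-"):
            strand = "?"
        # walk the CIGAR accumulating aligned run lengths between N segments
        pos = rec.reference_start
        anchor = 0  # reference-aligned bases since the last N (or read start)
        pending: list[tuple[int, int, int]] = []  # (start, end, left_anchor)
        malformed = False
        for op, length in cig:
            if length <= 0:
                malformed = True
                break
            if op in (0, 7, 8):  # M/=/X
                anchor += length
                pos += length
            elif op == 2:  # D: reference-consuming, counts toward the anchor
                anchor += length
                pos += length
            elif op == 3:  # N
                pending.append((pos, pos + length, anchor))
                pos += length
                anchor = 0
            elif op in (1, 4, 5, 6):  # I, S, H, P: no reference bases
                continue
            else:
                malformed = True
                break
        if malformed:
            n_bad += 1
            continue
        for idx, (start, end, left_anchor) in enumerate(pending):
            right_anchor = pending[idx + 1][2] if idx + 1 < len(pending) else anchor
            if left_anchor < min_anchor or right_anchor < min_anchor:
                continue
            if not (min_intron <= end - start <= max_intron):
                continue
            key = (rec.reference_name, start, end, strand)
            counts[key] = counts.get(key, 0) + 1
    if n_bad:
        warnings.warn(f"skipped {n_bad} records with malformed CIGAR", stacklevel=2)
    return [
        JunctionCount(contig=c, intron_start=s, intron_end=e, strand=st, n_reads=n)
        for (c, s, e, st), n in sorted(counts.items())
    ]


def merge_filter_junctions(
    per_sample: Sequence[Sequence[JunctionCount]], min_total: int = 10
) -> set[tuple[str, int, int, str]]:
    """Junction keys whose summed count across samples exceeds ``min_total``."""
    totals: dict[tuple[str, int, int, str], int] = {}
    for table in per_sample:
        for jc in table:
            totals[jc.key] = totals.get(jc.key, 0) + jc.n_reads
    return {key for key, total in totals.items() if total > min_total}


@dataclass(frozen=True)
class SpliceFraction:
    """Aberrant / (aberrant + canonical) split-read fraction from the exon-2 donor."""

    n_aberrant: int
    n_canonical: int
    fraction: float | None
    ci_low: float | None = None
    ci_high: float | None = None


def aberrant_splice_fraction(n_aberrant: int, n_canonical: int) -> SpliceFraction:
    """Per-sample aberrant-splicing fraction; missing when no exon-2 split reads."""
    if n_aberrant < 0 or n_canonical < 0:
        raise ValueError("counts must be non-negative")
    total = n_aberrant + n_canonical
    fraction = n_aberrant / total if total > 0 else None
    return SpliceFraction(n_aberrant=n_aberrant, n_canonical=n_canonical, fraction=fraction)


def combined_splice_fraction(
    counts: Sequence[tuple[int, int]],
    ci: bool = False,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> SpliceFraction:
    """Cohort-combined fraction: counts summed across samples before dividing.

    With ``ci=True`` a BCa interval over resampled samples is attached (the
    statistic being the combined fraction of the resampled cohort).
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("counts must be a sequence of (n_aberrant, n_canonical) pairs")
    n_ab = int(arr[:, 0].sum())
    n_can = int(arr[:, 1].sum())
    base = aberrant_splice_fraction(n_ab, n_can)
    if not ci or base.fraction is None:
        return base

    def stat(ab: np.ndarray, can: np.ndarray) -> float:
        tot = ab.sum() + can.sum()
        return ab.sum() / tot if tot > 0 else np.nan

    low, high = bca_interval(
        [arr[:, 0], arr[:, 1]], stat, n_boot=n_boot, alpha=alpha, seed=seed
    )
    return SpliceFraction(n_ab, n_can, base.fraction, ci_low=low, ci_high=high)


def sqtl_phenotype(n_aberrant: int, n_canonical: int) -> float:
    """Pseudocounted log-fraction phenotype for sQTL association.

    ln((a + 1) / ((a + 1) + (c + 1))), defined only for samples with at
    least one read spliced from the exon-2 donor; zero-total samples are the
    caller's to exclude and raise here.
    """
    if n_aberrant < 0 or n_canonical < 0:
        raise ValueError("counts must be non-negative")
    if n_aberrant + n_canonical < 1:
        raise ValueError("sample has no exon-2 split reads; exclude it")
    a = n_aberrant + 1
    c = n_canonical + 1
    return math.log(a / (a + c))


def detect_polya_softclips(
    records: Iterable,
    window: tuple[int, int],
    min_clip: int = 5,
    min_a_frac: float = 0.9,
    sense: str = "+",
) -> dict[int, int]:
    """Count adenine-rich terminal soft-clips per position inside ``window``.

    A read contributes at the reference position where its terminal
    soft-clip begins (the putative cleavage site) when the clip is at least
    ``min_clip`` bases and its adenine fraction is >= ``min_a_frac`` on the
    transcript sense strand ('A' for ``sense='+'``; reverse-complemented
    poly(A) reads present as leading 'T' clips for ``sense='-'``).
    """
    start, end = window
    counts: dict[int, int] = {}
    base = "A" if sense == "+" else "T"
    for rec in records:
        cig = rec.cigartuples
        seq = rec.query_sequence
        if not cig or not seq:
            continue
        candidates: list[tuple[int, str]] = []
        if sense == "+" and cig[-1][0] == 4:  # trailing clip at the 3' end
            clip_len = cig[-1][1]
            candidates.append((rec.reference_end, seq[-clip_len:]))
        if sense == "-" and cig[0][0] == 4:  # leading clip on antisense reads
            clip_len = cig[0][1]
            candidates.append((rec.reference_start, seq[:clip_len]))
        for pos, clip in candidates:
            if len(clip) < min_clip:
                continue
            frac = clip.upper().count(base) / len(clip)
            if frac >= min_a_frac and start <= pos < end:
                counts[pos] = counts.get(pos, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# BED12 junction interchange (regtools-style: blocks are the flanking anchors)


def write_junction_bed(
    junctions: Sequence[JunctionCount], path, anchor: int = 1, name_prefix: str = "JUNC"
) -> None:
    """Write junctions as BED12 with ``anchor``-sized blocks and score = count."""
    with open(path, "w") as fh:
        for k, jc in enumerate(junctions):
            chrom_start = jc.intron_start - anchor
            chrom_end = jc.intron_end + anchor
            fields = [
                jc.contig,
                str(chrom_start),
                str(chrom_end),
                f"{name_prefix}{k:05d}",
                str(jc.n_reads),
                jc.strand if jc.strand != "?" else ".",
                str(chrom_start),
                str(chrom_end),
                "255,0,0",
                "2",
                f"{anchor},{anchor}",
                f"0,{jc.intron_end - chrom_start}",
            ]
            fh.write("\t".join(fields) + "\n")


def read_junction_bed(path) -> list[JunctionCount]:
    """Invert :func:`write_junction_bed`: recover intron intervals from blocks."""
    out: list[JunctionCount] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom_start = int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            intron_start = chrom_start + starts[0] + sizes[0]
            intron_end = chrom_start + starts[1]
            strand = f[5] if f[5] in ("+", "-") else "?"
            out.append(
                JunctionCount(
                    contig=f[0],
                    intron_start=intron_start,
                    intron_end=intron_end,
                    strand=strand,
                    n_reads=int(f[4]),
                )
            )
    return out


def fraction_table(
    per_sample: Mapping[str, tuple[int, int]], dosages: Mapping[str, int] | None = None
) -> pd.DataFrame:
    """Tidy per-sample table of splice counts, fractions and (optionally) dosage."""
    rows = []
    for sample, (n_ab, n_can) in per_sample.items():
        sf = aberrant_splice_fraction(n_ab, n_can)
        rows.append(
            {
                "sample_id": sample,
                "n_aberrant": n_ab,
                "n_canonical": n_can,
                "fraction": sf.fraction,
                "dosage": dosages.get(sample) if dosages else None,
            }
        )
    return pd.DataFrame(rows)
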