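"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the library's own code paths: EHH by
explicit pairwise identity checks, evidence counting by a free-standing
single-record classifier, OLS by the normal equations.  They exist so the
production implementations can be checked against something that cannot
share their bugs.
"""

from __future__ import annotations

import numpy as np
import pytest

import svalocus as sv
from svalocus.haplotypes import HaplotypePanel
from svalocus.synthetic import SimRead


@pytest.fixture(scope="session")
def model() -> sv.LocusModel:
    return sv.build_locus_model()


@pytest.fixture(scope="session")
def locus(model) -> sv.InsertionLocusSpec:
    return sv.locus_spec_from_model(model)


def make_read(
    pos: int,
    cigar: str = "150M",
    contig: str = "miniASIP",
    mate_pos: int | None = None,
    tlen: int = 450,
    mapq: int = 60,
    is_read1: bool = True,
    proper_pair: bool = True,
    qcfail: bool = False,
    duplicate: bool = False,
    secondary: bool = False,
    name: str = "r",
    seq: str | None = None,
    tags: dict | None = None,
) -> SimRead:
    """Hand-build an alignment record from a CIGAR string."""
    ops = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "=": 7, "X": 8}
    tuples = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            tuples.append((ops[ch], int(num)))
            num = ""
    return SimRead(
        query_name=name,
        reference_name=contig,
        reference_start=pos,
        cigartuples=tuple(tuples),
        mapping_quality=mapq,
        template_length=tlen,
        next_reference_start=mate_pos if mate_pos is not None else pos + tlen - 150,
        is_reverse=not is_read1,
        is_read1=is_read1,
        is_proper_pair=proper_pair,
        is_qcfail=qcfail,
        is_duplicate=duplicate,
        is_secondary=secondary,
        mate_is_reverse=is_read1,
        query_sequence=seq,
        tags=dict(tags or {}),
    )


# ---------------------------------------------------------------------------
# EHH oracle: explicit pairwise identity over the inclusive interval


def brute_force_ehh(panel: HaplotypePanel, core_allele: int, variant_index: int) -> float:
    rows = np.nonzero(panel.alleles[:, panel.focal_index] == core_allele)[0]
    lo = min(panel.focal_index, variant_index)
    hi = max(panel.focal_index, variant_index)
    segment = panel.alleles[rows, lo : hi + 1]
    n = rows.size
    same = 0
    for a in range(n):
        for b in range(a + 1, n):
            if (segment[a] == segment[b]).all():
                same += 1
    return same / (n * (n - 1) // 2)


def random_panel(rng: np.random.Generator, n_hap=None, n_var=None) -> HaplotypePanel:
    n_hap = n_hap or int(rng.integers(4, 14))
    n_var = n_var or int(rng.integers(3, 25))
    while True:
        alleles = (rng.random((n_hap, n_var)) < rng.uniform(0.2, 0.8)).astype(np.int8)
        focal = int(rng.integers(0, n_var))
        counts = np.bincount(alleles[:, focal], minlength=2)
        if counts.min() >= 2:  # both core alleles usable
            return HaplotypePanel(
                alleles=alleles, positions=np.arange(n_var) * 100, focal_index=focal
            )


# ---------------------------------------------------------------------------
# Evidence-counting oracle: free-standing re-implementation, one record at a
# time, written against the published rule definitions.


def naive_count_evidence(records, locus, rules) -> tuple[int, int]:
    n_ins = 0
    anc_pairs: set[str] = set()
    for r in records:
        if r.is_unmapped or r.is_duplicate or r.is_secondary or r.is_supplementary or r.is_qcfail:
            continue
        rb = locus.right_breakpoint
        left = rb - r.reference_start
        right = (r.reference_end - 1) - rb
        spans = left >= rules.min_breakpoint_anchor and right >= rules.min_breakpoint_anchor
        clipped = any(op in (4, 5) for op, _ in r.cigartuples)
        if spans and not (rules.forbid_softclip and clipped):
            n_ins += 1
            continue
        if not r.is_paired or r.mate_is_unmapped:
            continue
        s, ms = r.reference_start, r.next_reference_start
        leftmost = s < ms or (s == ms and r.is_read1)
        if not leftmost:
            continue
        if abs(r.template_length) <= locus.tlen_threshold:
            continue
        if rules.strict_evidence:
            ok = s < locus.ins_start and ms >= locus.ins_end
        else:
            lo = locus.ins_start - locus.flank_window
            hi = locus.ins_end + locus.flank_window
            ok = lo <= s < hi and lo <= ms < hi
        if ok:
            anc_pairs.add(r.query_name)
    return n_ins, len(anc_pairs)


def random_stream(rng: np.random.Generator, locus, n_pairs=30) -> list[SimRead]:
    """Random, deliberately messy record stream around the locus."""
    reads: list[SimRead] = []
    for k in range(n_pairs):
        s = int(rng.integers(locus.ins_start - 3000, locus.ins_end + 3000))
        flen = int(rng.integers(300, 5000))
        cigar = "150M" if rng.random() < 0.7 else f"{int(rng.integers(100, 148))}M{int(rng.integers(2, 50))}S"
        for ridx, pos in enumerate((s, s + flen - 150)):
            reads.append(
                make_read(
                    pos,
                    cigar=cigar if ridx == 0 or rng.random() < 0.5 else "150M",
                    contig=locus.contig,
                    mate_pos=s + flen - 150 if ridx == 0 else s,
                    tlen=flen if ridx == 0 else -flen,
                    is_read1=ridx == 0,
                    duplicate=rng.random() < 0.05,
                    secondary=rng.random() < 0.05,
                    qcfail=rng.random() < 0.05,
                    name=f"q{k}",
                )
            )
    return reads
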