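"""IBD2 sibling identification and cross-sibling genotype concordance.

A sibling pair that shares both haplotypes identically by descent (IBD2)
over a window must have matching genotypes there up to genotyping error, so
the local mismatch count doubles as an accuracy estimator: pairs with at
most three mismatching array genotypes in a 2-Mb window are flagged IBD2,
and the concordance (and squared Pearson correlation) of an independent
genotype call across the flagged pairs estimates that call's accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SibPairResult", "flag_ibd2_pairs", "genotype_concordance", "pair_table"]

IBD2_MAX_MISMATCH = 3


@dataclass(frozen=True)
class SibPairResult:
    pair_id: str
    n_mismatch: int
    ibd2: bool
    call_a: str | None = None  # the pair's focal-variant genotype calls,
    call_b: str | None = None  # attached by the pipeline for reporting

    def __post_init__(self) -> None:
        if self.ibd2 != (self.n_mismatch <= IBD2_MAX_MISMATCH):
            raise ValueError("ibd2 flag inconsistent with mismatch count")


def flag_ibd2_pairs(
    geno_a: np.ndarray,
    geno_b: np.ndarray,
    positions: np.ndarray,
    center: int,
    window: int = 2_000_000,
    max_mismatch: int = IBD2_MAX_MISMATCH,
) -> list[SibPairResult]:
    """Flag pairs with <= ``max_mismatch`` genotype mismatches near ``center``.

    Mismatches are counted over variants inside [center - window/2,
    center + window/2); missing genotypes (negative or NaN) never count as
    mismatches.  Matrices are pairs x variants, aligned row-for-row.
    """
    geno_a = np.asarray(geno_a, dtype=float)
    geno_b = np.asarray(geno_b, dtype=float)
    positions = np.asarray(positions)
    if geno_a.shape != geno_b.shape:
        raise ValueError("sibling matrices must have identical shape")
    if positions.shape != (geno_a.shape[1],):
        raise ValueError("positions must have one entry per variant column")
    half = window // 2
    in_window = (positions >= center - half) & (positions < center + half)
    if not in_window.any():
        raise ValueError("no variants inside the window; mismatch count uninformative")
    a = geno_a[:, in_window]
    b = geno_b[:, in_window]
    valid = ~(np.isnan(a) | np.isnan(b) | (a < 0) | (b < 0))
    mismatches = ((a != b) & valid).sum(axis=1).astype(int)
    return [
        SibPairResult(pair_id=f"P{k}", n_mismatch=int(m), ibd2=bool(m <= max_mismatch))
        for k, m in enumerate(mismatches)
    ]


def genotype_concordance(
    calls_a: np.ndarray, calls_b: np.ndarray
) -> tuple[float, float]:
    """(fraction identical, squared Pearson r of dosages) across pairs.

    Pairs where either call is missing (NaN) are dropped first.  If either
    remaining vector is constant the correlation is undefined and returned
    as NaN (the fraction is still meaningful).
    """
    a = np.asarray(calls_a, dtype=float)
    b = np.asarray(calls_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("call vectors must be 1-D and of equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValueError("need at least 2 jointly called pairs")
    fraction = float(np.mean(a == b))
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return fraction, float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return fraction, float(r**2)


def pair_table(results: list[SibPairResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair_id": [r.pair_id for r in results],
            "n_mismatch": [r.n_mismatch for r in results],
            "ibd2": [r.ibd2 for r in results],
            "call_a": [r.call_a for r in results],
            "call_b": [r.call_b for r in results],
        }
    )
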