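"""Exon/intron expression quantification and allelic fold change estimation.

The expression pipeline mirrors a GTEx-style workflow: RNA-seq reads are
filtered (proper pair, vendor-QC pass, edit distance <= 6, MAPQ 255) and
counted per region with split-aware overlap; each sample's count-to-TPM
scaling factor is recovered from a highly expressed reference gene as

    scaling factor = read counts / (effective gene length * TPM)

and region-level TPMs follow as (count / region length) / factor.  Genotype
effects on expression are fit by ordinary least squares

    y = beta0 + beta_g * g + X_cov @ beta_cov + eps

where the intercept beta0 estimates the expression of two reference alleles
and beta_g the per-allele difference (alternate - reference), so the allelic
fold change is aFC = 2*beta_g/beta0 + 1 with both allelic expressions
constrained positive.  Confidence intervals use the bias-corrected and
accelerated (BCa) bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "RnaFilterSpec",
    "RegionQuant",
    "EqtlFit",
    "AfcEstimate",
    "count_region_reads",
    "tpm_scaling_factor",
    "region_tpm",
    "fit_eqtl_linear",
    "estimate_afc",
    "bca_interval",
    "read_gct",
    "write_gct",
]


@dataclass(frozen=True)
class RnaFilterSpec:
    """RNA-seq alignment filters (GTEx conventions).

    A record is kept iff it is in a proper pair, does not fail vendor
    quality checks, has edit distance (NM tag) <= ``max_edit_distance`` and
    mapping quality exactly ``required_mapq`` (255 marks unique alignments
    in STAR output).
    """

    max_edit_distance: int = 6
    required_mapq: int = 255

    def keep(self, rec) -> bool:
        if rec.is_unmapped or not rec.is_proper_pair or rec.is_qcfail:
            return False
        if rec.mapping_quality != self.required_mapq:
            return False
        try:
            nm = rec.get_tag("NM")
        except (KeyError, AttributeError):
            raise MissingEditDistance(getattr(rec, "query_name", "<record>"))
        return nm <= self.max_edit_distance


class MissingEditDistance(Exception):
    """Raised internally when a record lacks the NM tag."""


@dataclass
class RegionQuant:
    """Per-region read count and normalized expression."""

    region_id: str
    start: int
    end: int
    read_count: int = 0
    tpm: float | None = None

    @property
    def region_length(self) -> int:
        if self.end <= self.start:
            raise ValueError(f"region {self.region_id} has non-positive length")
        return self.end - self.start


def _aligned_blocks(rec) -> list[tuple[int, int]]:
    """Reference-consuming aligned blocks (M/=/X runs), split at N skips."""
    blocks: list[tuple[int, int]] = []
    pos = rec.reference_start
    cur_start = None
    for op, length in rec.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            if cur_start is None:
                cur_start = pos
            pos += length
        elif op == 2:  # D consumes reference but stays within a block
            pos += length
        elif op == 3:  # N closes the current block
            if cur_start is not None:
                blocks.append((cur_start, pos))
                cur_start = None
            pos += length
        # I, S, H, P consume no reference
    if cur_start is not None:
        blocks.append((cur_start, pos))
    return blocks


def count_region_reads(
    records: Iterable,
    regions: Sequence[RegionQuant],
    filters: RnaFilterSpec = RnaFilterSpec(),
) -> tuple[list[RegionQuant], int]:
    """Split-aware per-region read counts.

    A read contributes to a region iff any aligned block overlaps it by at
    least one base (a spliced read whose N gap spans the region does not
    count).  Each read counts at most once per region.  Records lacking an
    NM tag are excluded; the number of such exclusions is returned alongside
    the counts.
    """
    out = [RegionQuant(r.region_id, r.start, r.end, 0, r.tpm) for r in regions]
    n_warned = 0
    for rec in records:
        try:
            if not filters.keep(rec):
                continue
        except MissingEditDistance:
            n_warned += 1
            continue
        blocks = _aligned_blocks(rec)
        for region in out:
            if any(b_start < region.end and b_end > region.start for b_start, b_end in blocks):
                region.read_count += 1
    if n_warned:
        warnings.warn(f"{n_warned} records lacked an NM tag and were excluded", stacklevel=2)
    return out, n_warned


def tpm_scaling_factor(read_counts: float, effective_length: float, tpm: float) -> float:
    """Per-sample count-to-TPM scaling factor from a reference gene."""
    if read_counts <= 0 or effective_length <= 0 or tpm <= 0:
        raise ValueError("read_counts, effective_length and tpm must all be positive")
    return read_counts / (effective_length * tpm)


def region_tpm(read_count: float, region_length: float, factor: float) -> float:
    """Region TPM: length-normalized count divided by the sample factor."""
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    if factor <= 0:
        raise ValueError("scaling factor must be positive")
    if read_count < 0:
        raise ValueError("read_count must be non-negative")
    return (read_count / region_length) / factor


@dataclass(frozen=True)
class EqtlFit:
    """OLS fit of expression on genotype dosage plus covariates."""

    beta0: float
    beta_g: float
    beta_cov: np.ndarray
    residual_sd: float
    n: int
    se_beta_g: float


def fit_eqtl_linear(
    y: np.ndarray, g: np.ndarray, X_cov: np.ndarray | None = None
) -> EqtlFit:
    """Fit y = beta0 + beta_g*g + X_cov@beta_cov + eps by OLS.

    Conditional analyses are expressed by appending the conditioning
    variant's dosage as a covariate column.  Rank-deficient design matrices
    raise, naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if y.shape != g.shape or y.ndim != 1:
        raise ValueError("y and g must be 1-D vectors of equal length")
    if np.ptp(g) == 0:
        raise ValueError("genotype vector is constant")
    cols = [np.ones_like(y), g]
    names = ["intercept", "genotype"]
    if X_cov is not None and np.size(X_cov) > 0:
        X_cov = np.atleast_2d(np.asarray(X_cov, dtype=float))
        if X_cov.shape[0] != y.size:
            X_cov = X_cov.T
        if X_cov.shape[0] != y.size:
            raise ValueError("covariate matrix row count does not match samples")
        cols.extend(X_cov[:, k] for k in range(X_cov.shape[1]))
        names.extend(f"cov{k}" for k in range(X_cov.shape[1]))
    X = np.column_stack(cols)
    if y.size <= X.shape[1]:
        raise ValueError("need more samples than predictors")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        bad = [
            names[k]
            for k in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, k, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    model = sm.OLS(y, X).fit()
    resid_dof = max(int(model.df_resid), 1)
    return EqtlFit(
        beta0=float(model.params[0]),
        beta_g=float(model.params[1]),
        beta_cov=np.asarray(model.params[2:], dtype=float),
        residual_sd=float(np.sqrt(model.ssr / resid_dof)),
        n=int(y.size),
        se_beta_g=float(model.bse[1]),
    )


@dataclass(frozen=True)
class AfcEstimate:
    afc: float
    ci_low: float
    ci_high: float
    n_boot: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.afc <= self.ci_high):
            raise ValueError("aFC point estimate must lie inside its CI")


def estimate_afc(fit: EqtlFit) -> float:
    """Allelic fold change aFC = 2*beta_g/beta0 + 1 with positivity clamps.

    Reference-allele expression r = beta0 and alternate a = beta0 + 2*beta_g
    are each clamped below at eps = 1e-6 * max(|beta0|, 1) before forming
    a/r, absorbing degenerate fits rather than erroring.
    """
    eps = 1e-6 * max(abs(fit.beta0), 1.0)
    ref = max(fit.beta0, eps)
    alt = max(fit.beta0 + 2.0 * fit.beta_g, eps)
    return alt / ref


def bca_interval(
    data: Sequence[np.ndarray] | np.ndarray,
    statistic: Callable[..., float],
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[float, float]:
    """BCa bootstrap interval for ``statistic`` over jointly resampled samples.

    ``data`` is one array or a sequence of arrays sharing the sample axis;
    rows are resampled together (paired bootstrap).  Bias correction z0 comes
    from the bootstrap distribution and acceleration from the jackknife.  A
    degenerate bootstrap distribution (all replicates equal) yields a point
    interval with a warning.
    """
    arrays = [np.asarray(data)] if isinstance(data, np.ndarray) else [np.asarray(a) for a in data]
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays):
        raise ValueError("all data arrays must share the sample axis")
    if n < 10:
        raise ValueError("need at least 10 samples for a bootstrap interval")
    if n_boot < 1000:
        raise ValueError("n_boot must be at least 1000")

    point = float(statistic(*arrays))
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        # scipy warns when the BCa z0 is undefined for a degenerate
        # distribution; we handle that case explicitly below.
        warnings.simplefilter("ignore")
        res = scipy.stats.bootstrap(
            arrays,
            statistic,
            n_resamples=n_boot,
            confidence_level=1.0 - alpha,
            method="BCa",
            paired=len(arrays) > 1,
            vectorized=False,
            rng=rng,
        )
    dist = res.bootstrap_distribution
    if np.ptp(dist[np.isfinite(dist)]) == 0 or not np.isfinite(res.confidence_interval.low):
        warnings.warn("degenerate bootstrap distribution; returning point interval", stacklevel=2)
        return (point, point)
    return (float(res.confidence_interval.low), float(res.confidence_interval.high))


def afc_with_ci(
    y: np.ndarray,
    g: np.ndarray,
    X_cov: np.ndarray | None = None,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> AfcEstimate:
    """Point aFC from the full-sample fit plus a BCa CI over resampled donors."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    arrays: list[np.ndarray] = [y, g]
    if X_cov is not None and np.size(X_cov) > 0:
        X_cov = np.atleast_2d(np.asarray(X_cov, dtype=float))
        if X_cov.shape[0] != y.size:
            X_cov = X_cov.T
        arrays.extend(X_cov[:, k] for k in range(X_cov.shape[1]))

    def stat(*cols: np.ndarray) -> float:
        yy, gg, *cov = cols
        if np.ptp(gg) == 0:
            return np.nan
        X = np.column_stack([np.ones_like(yy), gg, *cov])
        beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
        eps = 1e-6 * max(abs(beta[0]), 1.0)
        return max(beta[0] + 2 * beta[1], eps) / max(beta[0], eps)

    point = float(stat(*arrays))
    low, high = bca_interval(arrays, stat, n_boot=n_boot, alpha=alpha, seed=seed)
    # Guard against MC noise placing the point epsilon outside the interval.
    low, high = min(low, point), max(high, point)
    return AfcEstimate(afc=point, ci_low=low, ci_high=high, n_boot=n_boot)


# ---------------------------------------------------------------------------
# GCT 1.2 expression matrices


def read_gct(path) -> pd.DataFrame:
    """Read a GCT 1.2 file into a DataFrame indexed by Name, with Description."""
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"not a GCT 1.2 file (header {version!r})")
        n_rows, n_cols = (int(x) for x in fh.readline().split()[:2])
        df = pd.read_csv(fh, sep="\t")
    if df.columns[0] != "Name" or df.columns[1] != "Description":
        raise ValueError("GCT must start with Name and Description columns")
    if len(df) != n_rows or df.shape[1] - 2 != n_cols:
        raise ValueError("GCT dimension line does not match table")
    return df.set_index("Name")


def write_gct(df: pd.DataFrame, path) -> None:
    """Write a DataFrame (indexed by Name, first column Description) as GCT 1.2."""
    if df.columns[0] != "Description":
        raise ValueError("first column must be Description")
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{len(df)}\t{df.shape[1] - 1}\n")
        df.to_csv(fh, sep="\t", index_label="Name")
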