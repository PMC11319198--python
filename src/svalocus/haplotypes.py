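"""Haplotype-based selection statistics around a focal variant.

Implements extended haplotype homozygosity (EHH), haplotype bifurcation
structure, pairwise LD (r^2) on phased panels, and per-population allele
frequencies from genotype calls.  EHH at a variant j is the probability that
two randomly drawn haplotypes carrying the core allele at the focal variant
are identical at every variant between the focal variant and j (inclusive);
slow decay of EHH with distance is the classic signature of a recent
positive-selection sweep on the core haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypePanel",
    "EhhCurve",
    "BifurcationNode",
    "ehh_curve",
    "bifurcation_counts",
    "ld_r2",
    "allele_frequencies",
]


@dataclass(frozen=True)
class HaplotypePanel:
    """Binary allele matrix (haplotypes x variants) with a focal variant.

    ``alleles`` entries must be 0/1 and complete (no missing data; phased
    input is assumed and enforced at construction).  ``positions`` are
    base-pair coordinates, strictly increasing, one per variant column.
    """

    alleles: np.ndarray
    positions: np.ndarray
    focal_index: int
    population_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        alleles = np.asarray(self.alleles)
        positions = np.asarray(self.positions)
        object.__setattr__(self, "alleles", alleles)
        object.__setattr__(self, "positions", positions)
        if alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D haplotypes x variants matrix")
        if not np.isin(alleles, (0, 1)).all():
            raise ValueError("panel alleles must be 0/1 with no missing entries")
        if positions.shape != (alleles.shape[1],):
            raise ValueError("positions must have one entry per variant")
        if alleles.shape[1] > 1 and not (np.diff(positions) > 0).all():
            raise ValueError("positions must be strictly increasing")
        if not 0 <= self.focal_index < alleles.shape[1]:
            raise ValueError("focal_index out of range")
        if self.population_labels is not None and len(self.population_labels) != alleles.shape[0]:
            raise ValueError("population_labels must have one entry per haplotype")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_variants(self) -> int:
        return self.alleles.shape[1]


@dataclass(frozen=True)
class EhhCurve:
    """EHH values indexed by variant, centred on the panel's focal variant."""

    core_allele: int
    variant_indices: np.ndarray
    ehh_values: np.ndarray

    def value_at(self, variant_index: int) -> float:
        hit = np.nonzero(self.variant_indices == variant_index)[0]
        if hit.size == 0:
            raise KeyError(f"variant index {variant_index} not on curve")
        return float(self.ehh_values[hit[0]])


@dataclass
class BifurcationNode:
    """One node of a haplotype bifurcation tree.

    ``variant_index`` is the most recently incorporated variant (the focal
    variant at the root); ``size`` is the number of core haplotypes in this
    identity class; child class sizes always sum to the parent size.
    """

    variant_index: int
    size: int
    children: list["BifurcationNode"] = field(default_factory=list)

    def leaf_sizes(self) -> list[int]:
        if not self.children:
            return [self.size]
        out: list[int] = []
        for child in self.children:
            out.extend(child.leaf_sizes())
        return out


def _core_rows(panel: HaplotypePanel, core_allele: int) -> np.ndarray:
    if core_allele not in (0, 1):
        raise ValueError("core_allele must be 0 or 1")
    rows = np.nonzero(panel.alleles[:, panel.focal_index] == core_allele)[0]
    if rows.size < 2:
        raise ValueError(
            f"need at least 2 haplotypes carrying core allele {core_allele}; found {rows.size}"
        )
    return rows


def _homozygosity(group_ids: np.ndarray) -> float:
    """Probability two distinct haplotypes fall in the same identity class."""
    n = group_ids.size
    _, counts = np.unique(group_ids, return_counts=True)
    pairs = (counts * (counts - 1) // 2).sum()
    return float(pairs) / (n * (n - 1) // 2)


def _refine(group_ids: np.ndarray, column: np.ndarray) -> np.ndarray:
    # Re-factorize (group, allele) pairs into dense new group ids.
    combined = group_ids.astype(np.int64) * 2 + column.astype(np.int64)
    _, new_ids = np.unique(combined, return_inverse=True)
    return new_ids


def ehh_curve(panel: HaplotypePanel, core_allele: int) -> EhhCurve:
    """EHH of ``core_allele`` carriers at each variant, outward from the focal.

    For a variant j left or right of the focal variant, carriers are
    partitioned by their allele vector over the inclusive interval
    [focal, j]; EHH(j) = sum_h C(n_h, 2) / C(n_core, 2) over identity
    classes h.  Each direction is computed independently and the curve is
    truncated once EHH reaches 0 (it cannot recover).
    """
    rows = _core_rows(panel, core_allele)
    sub = panel.alleles[rows, :]
    focal = panel.focal_index

    def one_side(indices: range) -> tuple[list[int], list[float]]:
        idx_out: list[int] = []
        vals: list[float] = []
        group_ids = np.zeros(rows.size, dtype=np.int64)
        for j in indices:
            group_ids = _refine(group_ids, sub[:, j])
            value = _homozygosity(group_ids)
            idx_out.append(j)
            vals.append(value)
            if value == 0.0:
                break
        return idx_out, vals

    left_idx, left_vals = one_side(range(focal - 1, -1, -1))
    right_idx, right_vals = one_side(range(focal + 1, panel.n_variants))

    indices = np.array(left_idx[::-1] + [focal] + right_idx, dtype=np.int64)
    values = np.array(left_vals[::-1] + [1.0] + right_vals, dtype=float)
    return EhhCurve(core_allele=core_allele, variant_indices=indices, ehh_values=values)


def bifurcation_counts(panel: HaplotypePanel, core_allele: int) -> dict[str, BifurcationNode]:
    """Bifurcation trees (left and right of the focal variant) for core carriers.

    Moving away from the focal variant, each variant that distinguishes
    haplotypes within an identity class splits the corresponding node; node
    sizes give the line weights of a classic bifurcation diagram.
    """
    rows = _core_rows(panel, core_allele)
    sub = panel.alleles[rows, :]
    focal = panel.focal_index

    def one_side(indices: range) -> BifurcationNode:
        root = BifurcationNode(variant_index=focal, size=rows.size)
        # leaves maps a node to the haplotype row indices (into sub) it holds
        leaves: list[tuple[BifurcationNode, np.ndarray]] = [(root, np.arange(rows.size))]
        for j in indices:
            new_leaves: list[tuple[BifurcationNode, np.ndarray]] = []
            for node, members in leaves:
                col = sub[members, j]
                split = [(allele, members[col == allele]) for allele in (0, 1)]
                split = [(a, m) for a, m in split if m.size > 0]
                if len(split) == 1:
                    # no bifurcation here; node simply extends
                    new_leaves.append((node, members))
                    continue
                for _, m in split:
                    child = BifurcationNode(variant_index=j, size=int(m.size))
                    node.children.append(child)
                    new_leaves.append((child, m))
            leaves = new_leaves
        return root

    return {
        "left": one_side(range(focal - 1, -1, -1)),
        "right": one_side(range(focal + 1, panel.n_variants)),
    }


def ld_r2(
    panel: HaplotypePanel,
    maf_min: float = 0.01,
    sample_n: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pairwise haplotype r^2 among (optionally down-sampled) common variants.

    Variants with minor allele frequency <= ``maf_min`` are removed before a
    seeded uniform draw (without replacement) of ``sample_n`` variants;
    r^2 = (p_AB - p_A p_B)^2 / (p_A (1-p_A) p_B (1-p_B)).  Monomorphic pairs
    are reported as missing (cannot arise after the MAF filter but kept for
    completeness).  Returns a table with columns i, j, pos_i, pos_j, r2.
    """
    freqs = panel.alleles.mean(axis=0)
    maf = np.minimum(freqs, 1.0 - freqs)
    kept = np.nonzero(maf > maf_min)[0]
    if kept.size < 2:
        raise ValueError("fewer than 2 variants pass the MAF filter")
    if sample_n is not None and sample_n < kept.size:
        rng = np.random.default_rng(seed)
        kept = np.sort(rng.choice(kept, size=sample_n, replace=False))

    sub = panel.alleles[:, kept].astype(float)
    p = sub.mean(axis=0)
    # joint frequency of the 1/1 haplotype for every pair
    p_ab = (sub.T @ sub) / sub.shape[0]
    d = p_ab - np.outer(p, p)
    denom = np.outer(p * (1 - p), p * (1 - p))
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, d**2 / denom, np.nan)

    iu, ju = np.triu_indices(kept.size, k=0)
    return pd.DataFrame(
        {
            "i": kept[iu],
            "j": kept[ju],
            "pos_i": panel.positions[kept[iu]],
            "pos_j": panel.positions[kept[ju]],
            "r2": r2[iu, ju],
        }
    )


def allele_frequencies(
    calls: pd.DataFrame, population_labels: pd.Series | np.ndarray | list[str]
) -> pd.DataFrame:
    """Insertion-allele frequency per population from a genotype-call table.

    ``calls`` must carry a ``dosage`` column (0/1/2 copies of the insertion
    allele, NaN for no-calls).  Frequency = sum(dosage) / (2 * n_called);
    no-calls are excluded from the denominator, and a population with zero
    called samples gets a missing frequency.
    """
    if len(calls) == 0:
        raise ValueError("calls table is empty")
    labels = pd.Series(np.asarray(population_labels), index=calls.index, name="population")
    df = pd.DataFrame({"dosage": calls["dosage"].astype(float), "population": labels})
    grouped = df.groupby("population", sort=True)["dosage"]
    n_called = grouped.count()
    freq = grouped.sum() / (2.0 * n_called)
    freq[n_called == 0] = np.nan
    out = pd.DataFrame({"n_called": n_called, "frequency": freq})
    return out.reset_index()


def curve_table(curves: list[EhhCurve], panel: HaplotypePanel) -> pd.DataFrame:
    """Flatten EHH curves to a tidy table (core_allele, variant, position, ehh)."""
    frames = []
    for curve in curves:
        frames.append(
            pd.DataFrame(
                {
                    "core_allele": curve.core_allele,
                    "variant_index": curve.variant_indices,
                    "position": panel.positions[curve.variant_indices],
                    "ehh": curve.ehh_values,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
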