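"""Distance-CDF enrichment, co-occupancy stratification, occupancy-expression
correlation, and the promoter-pausing signature.

Repressed genes lying near late binding events, rising promoter RNAP2 with
falling gene-body H3K36me3, and distance-stratified rank-sum contrasts are
the three integration readouts this module computes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core import GeneModel, PeakSet, nearest_distances

DEFAULT_CUTOFFS = tuple(int(x) for x in np.geomspace(1_000, 1_000_000, 13).round())
NEAR_BP = 10_000
FAR_BP = 100_000
EXACT_RANKSUM_MAX_N = 8


@dataclass(frozen=True)
class DistanceCDF:
    label: str
    cutoffs: tuple[int, ...]
    fractions: tuple[float, ...]
    n_genes: int

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions)
        if np.any(f < 0) or np.any(f > 1) or np.any(np.diff(f) < -1e-12):
            raise ValueError("CDF fractions must be non-decreasing within [0, 1]")


def gene_nearest_distances(genes: Sequence[GeneModel], sites: PeakSet) -> np.ndarray:
    """Per-gene distance from the closest TSS to the nearest site edge.

    Genes on chromosomes without sites get +inf.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {p.chrom for p in sites}:
        ps = [p for p in sites if p.chrom == chrom]
        by_chrom[chrom] = (
            np.array([p.interval.start for p in ps]),
            np.array([p.interval.end for p in ps]),
        )
    out = np.full(len(genes), np.inf)
    for i, g in enumerate(genes):
        if g.chrom not in by_chrom:
            continue
        starts, ends = by_chrom[g.chrom]
        d = nearest_distances(np.asarray(g.tss), starts, ends)
        out[i] = d.min()
    return out


def distance_cdf(
    genes: Sequence[GeneModel],
    sites: PeakSet,
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
    label: str = "target",
) -> DistanceCDF:
    """Cumulative fraction of genes whose nearest site lies within each cutoff."""
    cutoffs = tuple(int(c) for c in cutoffs)
    if not genes:
        raise ValueError("empty gene set")
    if any(c <= 0 for c in cutoffs) or list(cutoffs) != sorted(cutoffs):
        raise ValueError("cutoffs must be positive and ascending")
    d = gene_nearest_distances(genes, sites)
    fracs = tuple(float((d <= c).mean()) for c in cutoffs)
    return DistanceCDF(label, cutoffs, fracs, len(genes))


def background_cdf(
    all_genes: Sequence[GeneModel],
    sites: PeakSet,
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
) -> DistanceCDF:
    """Distance CDF over the full annotation (the genome-wide background)."""
    return distance_cdf(all_genes, sites, cutoffs, label="background")


def cdf_enrichment(target: DistanceCDF, background: DistanceCDF) -> tuple[float, float]:
    """(max signed vertical gap, mean signed difference) of target over background."""
    if target.cutoffs != background.cutoffs:
        raise ValueError("CDFs computed at different cutoffs")
    diff = np.asarray(target.fractions) - np.asarray(background.fractions)
    return float(diff.max()), float(diff.mean())


def stratify_by_cooccupancy(sites: PeakSet, mark: PeakSet, min_overlap_bp: int = 1) -> tuple[PeakSet, PeakSet]:
    """Partition sites into (co-occupied by the mark, devoid of the mark)."""
    with_mark, without = [], []
    for p in sites:
        (with_mark if mark.max_overlap_bp(p.interval) >= min_overlap_bp else without).append(p)
    return sites.with_peaks(with_mark), sites.with_peaks(without)


def occupancy_expression_correlation(
    promoter_rpm: Mapping[str, float],
    expression_rpkm: Mapping[str, float],
) -> float:
    """Spearman rho between promoter occupancy and expression over shared genes."""
    shared = sorted(set(promoter_rpm) & set(expression_rpkm))
    if len(shared) < 10:
        raise ValueError("need >= 10 shared genes")
    x = [promoter_rpm[g] for g in shared]
    y = [expression_rpkm[g] for g in shared]
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def concordance_fraction(
    genes: Iterable[str],
    direction: str,
    occupancy_ratio: Mapping[str, float],
) -> float:
    """Fraction of genes whose occupancy log-ratio sign matches RNA direction.

    Up genes need ratio > 0, down genes ratio < 0; exact zeros count as
    discordant.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    vals = np.array([occupancy_ratio[g] for g in genes])
    hit = vals > 0 if direction == "up" else vals < 0
    return float(hit.mean())


@dataclass(frozen=True)
class PausingCall:
    gene_id: str
    promoter_ratio: float  # log2 RNAP2 promoter occupancy, late vs control
    body_ratio: float  # log2 H3K36me3 gene-body occupancy, late vs control
    rna_direction: str
    mechanism: str  # pausing_consistent / reduced_initiation / indeterminate


def classify_repression_mechanism(
    gene_id: str,
    promoter_ratio: float,
    body_ratio: float,
    rna_direction: str,
) -> PausingCall:
    """Mechanism label for one repressed gene.

    Rising promoter RNAP2 with falling gene-body elongation mark in a gene
    whose mRNA falls is the promoter-proximal pausing signature; falling
    promoter signal with falling body signal indicates reduced initiation.
    """
    if rna_direction != "down":
        raise ValueError("pausing classifier is defined for repressed (down) genes only")
    if promoter_ratio > 0 and body_ratio < 0:
        mech = "pausing_consistent"
    elif promoter_ratio < 0 and body_ratio < 0:
        mech = "reduced_initiation"
    else:
        mech = "indeterminate"
    return PausingCall(gene_id, promoter_ratio, body_ratio, rna_direction, mech)


@dataclass(frozen=True)
class StrataTestResult:
    near: tuple[float, ...]
    far: tuple[float, ...]
    statistic: float  # rank sum of the near group
    p: float
    method: str  # exact / normal


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum test.

    Exact by full enumeration of group assignments when min(n) <= 8
    (midranks handle ties); otherwise the normal approximation with tie
    and continuity corrections (Mann-Whitney).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w = float(ranks[:n1].sum())
    if min(n1, n2) <= EXACT_RANKSUM_MAX_N:
        mean = n1 * (n1 + n2 + 1) / 2.0
        dev = abs(w - mean)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            total += 1
            ws = ranks[list(combo)].sum()
            if abs(ws - mean) >= dev - 1e-12:
                count += 1
        return w, count / total, "exact"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                             use_continuity=True)
    return w, float(res.pvalue), "normal"


def stratified_ratio_test(
    ratios: Mapping[str, float],
    near_genes: Iterable[str],
    far_genes: Iterable[str],
) -> StrataTestResult:
    """Rank-sum contrast of gene-body ratios between near and far strata."""
    near = [g for g in near_genes]
    far = [g for g in far_genes]
    if set(near) & set(far):
        raise ValueError("near and far gene groups must be disjoint")
    if min(len(near), len(far)) < 3:
        raise ValueError("each stratum needs >= 3 genes")
    xv = [ratios[g] for g in near]
    yv = [ratios[g] for g in far]
    w, p, method = rank_sum_test(xv, yv)
    return StrataTestResult(tuple(xv), tuple(yv), w, p, method)


def assign_strata(
    genes: Sequence[GeneModel],
    sites: PeakSet,
    near_bp: int = NEAR_BP,
    far_bp: int = FAR_BP,
) -> tuple[list[str], list[str]]:
    """Split genes into near (< near_bp) and far (> far_bp) strata.

    Genes in [near_bp, far_bp] are excluded; bounds exclusive.
    """
    d = gene_nearest_distances(genes, sites)
    near = [g.gene_id for g, dd in zip(genes, d) if dd < near_bp]
    far = [g.gene_id for g, dd in zip(genes, d) if dd > far_bp]
    return near, far


__all__ = [
    "DistanceCDF",
    "PausingCall",
    "StrataTestResult",
    "DEFAULT_CUTOFFS",
    "gene_nearest_distances",
    "distance_cdf",
    "background_cdf",
    "cdf_enrichment",
    "stratify_by_cooccupancy",
    "occupancy_expression_correlation",
    "concordance_fraction",
    "classify_repression_mechanism",
    "rank_sum_test",
    "stratified_ratio_test",
    "assign_strata",
]
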