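"""Genomic coordinate conventions, interval containers, and annotation model.

All coordinates are 0-based, half-open ``[start, end)`` — BED semantics.
GTF input (1-based, closed) is converted on read by :mod:`cistrodyn.io`.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


class ValidationError(ValueError):
    """A genomic object violates a coordinate or bounds invariant."""


class GenomeModel(Mapping):
    """Chromosome name -> length in bp.

    Behaves as a read-only mapping; rejects duplicate names and
    non-positive lengths.
    """

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = list(sizes.items()) if isinstance(sizes, Mapping) else list(sizes)
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names")
        for name, length in items:
            if int(length) <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length}")
        self._sizes = {str(n): int(l) for n, l in items}

    def __getitem__(self, name: str) -> int:
        return self._sizes[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenomeModel({self._sizes!r})"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def validate_against(self, genome: GenomeModel) -> None:
        if self.chrom not in genome:
            raise ValidationError(f"unknown chromosome {self.chrom!r}")
        if self.end > genome[self.chrom]:
            raise ValidationError(
                f"{self.chrom}:{self.start}-{self.end} exceeds chromosome "
                f"length {genome[self.chrom]}"
            )


@dataclass(frozen=True)
class Peak:
    """A called binding site: an interval plus a summit offset and score.

    ``summit`` is the bp offset of the point of maximal signal from
    ``interval.start``; ``score`` is a unitless enrichment value.
    """

    interval: GenomicInterval
    summit: int
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.summit < len(self.interval)):
            raise ValidationError(
                f"summit offset {self.summit} outside peak of length {len(self.interval)}"
            )

    @property
    def summit_abs(self) -> int:
        """Absolute genomic position of the summit."""
        return self.interval.start + self.summit

    @property
    def chrom(self) -> str:
        return self.interval.chrom


class PeakSet:
    """Ordered collection of peaks for one factor/condition/time point."""

    def __init__(
        self,
        peaks: Iterable[Peak],
        factor: str = "",
        timepoint: float | None = None,
        replicate: str = "",
        genome: GenomeModel | None = None,
    ):
        self.peaks: list[Peak] = list(peaks)
        self.factor = factor
        self.timepoint = timepoint
        self.replicate = replicate
        if genome is not None:
            for p in self.peaks:
                p.interval.validate_against(genome)
        self._trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def _tree(self, chrom: str) -> IntervalTree:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for p in self.peaks:
                trees.setdefault(p.chrom, IntervalTree()).addi(
                    p.interval.start, p.interval.end, p
                )
            self._trees = trees
        return self._trees.get(chrom, IntervalTree())

    def max_overlap_bp(self, iv: GenomicInterval) -> int:
        """Largest bp overlap between ``iv`` and any peak in the set."""
        best = 0
        for hit in self._tree(iv.chrom).overlap(iv.start, iv.end):
            best = max(best, min(hit.end, iv.end) - max(hit.begin, iv.start))
        return best

    def with_peaks(self, peaks: Iterable[Peak]) -> "PeakSet":
        return PeakSet(peaks, self.factor, self.timepoint, self.replicate)

    def sorted(self) -> "PeakSet":
        return self.with_peaks(
            sorted(self.peaks, key=lambda p: (p.chrom, p.interval.start, p.interval.end))
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with one TSS and one gene-body interval per transcript."""

    gene_id: str
    chrom: str
    strand: str
    tss: tuple[int, ...]
    bodies: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.tss) < 1:
            raise ValidationError(f"gene {self.gene_id}: at least one TSS required")
        if any(t < 0 for t in self.tss):
            raise ValidationError(f"gene {self.gene_id}: negative TSS")


# ---------------------------------------------------------------------------
# interval operations


def reproducible_peaks(rep1: PeakSet, rep2: PeakSet, min_overlap_bp: int = 1) -> PeakSet:
    """Peaks of ``rep1`` supported by >= ``min_overlap_bp`` overlap in ``rep2``.

    Summit and score are taken from ``rep1``. Empty inputs give an empty
    output rather than an error.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    kept = [p for p in rep1 if rep2.max_overlap_bp(p.interval) >= min_overlap_bp]
    return rep1.with_peaks(kept)


def summit_window(peak: Peak, width: int = 100, genome: GenomeModel | None = None) -> GenomicInterval:
    """The ``width``-bp window centered on the peak summit, clipped to bounds."""
    if width < 2 or width % 2:
        raise ValueError("width must be even and >= 2")
    half = width // 2
    start = max(0, peak.summit_abs - half)
    end = peak.summit_abs + half
    if genome is not None and peak.chrom in genome:
        end = min(end, genome[peak.chrom])
    return GenomicInterval(peak.chrom, start, end, peak.interval.strand)


def promoter_of(gene: GeneModel, flank: int = 500, genome: GenomeModel | None = None) -> list[GenomicInterval]:
    """Symmetric promoter windows ``[TSS - flank, TSS + flank)``, one per TSS.

    Strand does not change the window extent.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    out = []
    for t in gene.tss:
        start = max(0, t - flank)
        end = t + flank
        if genome is not None and gene.chrom in genome:
            end = min(end, genome[gene.chrom])
        out.append(GenomicInterval(gene.chrom, start, end, gene.strand))
    return out


def interval_point_distance(point: int, start: int, end: int) -> int:
    """Distance from a point to the nearest edge of ``[start, end)``.

    Zero when the point lies inside the interval; measured to the first
    (``start``) or last (``end - 1``) covered base otherwise.
    """
    if point < start:
        return start - point
    if point >= end:
        return point - (end - 1)
    return 0


def nearest_site_distance(point: int, chrom: str, sites: PeakSet) -> float:
    """Distance from a position to the nearest peak edge on its chromosome.

    Returns ``math.inf`` when the chromosome carries no site.
    """
    chrom_sites = [p for p in sites if p.chrom == chrom]
    if not chrom_sites:
        return math.inf
    starts = np.array([p.interval.start for p in chrom_sites])
    ends = np.array([p.interval.end for p in chrom_sites])
    d = np.where(point < starts, starts - point, np.where(point >= ends, point - (ends - 1), 0))
    return float(d.min())


def nearest_distances(points: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Vectorized nearest-edge distances for many points against one site list."""
    if starts.size == 0:
        return np.full(points.shape, np.inf)
    p = points[:, None]
    d = np.where(p < starts, starts - p, np.where(p >= ends, p - (ends - 1), 0))
    return d.min(axis=1).astype(float)


def overlap_fraction(a: PeakSet, b: PeakSet, min_overlap_bp: int = 1) -> float:
    """Fraction of ``a``'s peaks overlapped by >= ``min_overlap_bp`` with ``b``.

    The inverse comparison (fraction of ``b`` overlapped by ``a``) is
    obtained by swapping the arguments.
    """
    if len(a) == 0:
        raise ValueError("overlap_fraction undefined for an empty first set")
    n = sum(1 for p in a if b.max_overlap_bp(p.interval) >= min_overlap_bp)
    return n / len(a)


__all__ = [
    "GenomeModel",
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "GeneModel",
    "ValidationError",
    "reproducible_peaks",
    "summit_window",
    "promoter_of",
    "interval_point_distance",
    "nearest_site_distance",
    "nearest_distances",
    "overlap_fraction",
]
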