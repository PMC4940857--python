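"""Normalized read-depth quantification and ratio statistics.

Occupancy is expressed in reads per million aligned reads (RPM): raw
region counts divided by the library's total aligned reads times 1e6.
Ratios between conditions are log2 with an additive RPM pseudocount so
empty regions stay finite.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel, GenomicInterval


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one ChIP-seq library."""

    sample_id: str
    factor: str
    timepoint: float
    replicate: str
    total_aligned_reads: int

    def __post_init__(self) -> None:
        if self.total_aligned_reads <= 0:
            raise ValueError("total_aligned_reads must be positive")


class Coverage:
    """Per-base coverage source; subclasses supply ``region_sum``."""

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        raise NotImplementedError


class ArrayCoverage(Coverage):
    """In-memory per-chromosome coverage arrays (synthetic data, tests)."""

    def __init__(self, arrays: Mapping[str, np.ndarray]):
        self.arrays = {c: np.asarray(a, dtype=float) for c, a in arrays.items()}

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        if chrom not in self.arrays:
            raise KeyError(f"chromosome {chrom!r} absent from coverage")
        a = self.arrays[chrom]
        return float(a[start:min(end, a.size)].sum())


class BedGraphCoverage(ArrayCoverage):
    """Coverage loaded from a bedGraph file (whole chromosomes in memory)."""

    def __init__(self, path: str | os.PathLike, genome: Mapping[str, int]):
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "value"], comment="#")
        arrays = {c: np.zeros(genome[c]) for c in genome}
        for row in df.itertuples(index=False):
            arrays[row.chrom][int(row.start):int(row.end)] += float(row.value)
        super().__init__(arrays)


class BigWigCoverage(Coverage):
    def __init__(self, path: str | os.PathLike):
        import pyBigWig

        self.bw = pyBigWig.open(str(path))

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        if chrom not in self.bw.chroms():
            raise KeyError(f"chromosome {chrom!r} absent from coverage")
        vals = self.bw.values(chrom, start, end, numpy=True)
        return float(np.nansum(vals))


def count_reads(regions: Sequence[GenomicInterval], coverage: Coverage) -> np.ndarray:
    """Per-region signal totals (per-base sum over the region).

    For read-resolved sources, upstream tooling should first reduce reads
    to a coverage track of 5' ends; the sum then equals a read count.
    """
    return np.array([coverage.region_sum(iv.chrom, iv.start, iv.end) for iv in regions])


def normalize_depth(counts: np.ndarray | float, meta: SampleMeta) -> np.ndarray | float:
    """counts -> RPM given the sample's total aligned reads."""
    return np.asarray(counts, dtype=float) / meta.total_aligned_reads * 1e6


def depth_ratio(a, b, pseudocount: float = 1.0):
    """log2((a + pc) / (b + pc)); positive means the first argument is stronger."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("RPM values must be non-negative")
    out = np.log2((a + pseudocount) / (b + pseudocount))
    return float(out) if out.ndim == 0 else out


class OccupancyMatrix:
    """Sites/regions x samples matrix of RPM values with sample metadata.

    ``regions`` optionally maps each row to genomic context
    (columns: region_id, chrom, start, end, gene_id, kind).
    """

    def __init__(
        self,
        values: pd.DataFrame,
        samples: Mapping[str, SampleMeta],
        regions: pd.DataFrame | None = None,
    ):
        missing = set(values.columns) - set(samples)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        arr = values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("occupancy values must be finite and non-negative")
        self.values = values
        self.samples = dict(samples)
        self.regions = regions

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        samples: Mapping[str, SampleMeta],
        regions: pd.DataFrame | None = None,
    ) -> "OccupancyMatrix":
        rpm = counts.astype(float).copy()
        for sid in rpm.columns:
            rpm[sid] = normalize_depth(rpm[sid].to_numpy(), samples[sid])
        return cls(rpm, samples, regions)

    def sample_ids(self, factor: str | None = None, timepoint: float | None = None) -> list[str]:
        out = []
        for sid, m in self.samples.items():
            if factor is not None and m.factor != factor:
                continue
            if timepoint is not None and m.timepoint != timepoint:
                continue
            out.append(sid)
        return out

    def mean_rpm(self, sample_ids: Sequence[str]) -> pd.Series:
        return self.values[list(sample_ids)].mean(axis=1)

    def to_tsv(self, path: str | os.PathLike, header_lines: Iterable[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.values.to_csv(fh, sep="\t", index_label="region_id")


def replicate_concordance(matrix: OccupancyMatrix, sample_a: str, sample_b: str) -> float:
    """Spearman rank correlation of two samples' RPM over shared regions."""
    x = matrix.values[sample_a].to_numpy()
    y = matrix.values[sample_b].to_numpy()
    if x.size < 3:
        raise ValueError("replicate concordance needs >= 3 shared regions")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def majority_direction(ratios: np.ndarray) -> tuple[float, float, float]:
    """Fractions of regions with log-ratio > 0, < 0 and == 0 (sums to 1)."""
    r = np.asarray(ratios, dtype=float)
    if r.size == 0:
        raise ValueError("empty ratio vector")
    n = r.size
    return (float((r > 0).sum() / n), float((r < 0).sum() / n), float((r == 0).sum() / n))


def strongest_region_for_gene(
    gene: GeneModel | str,
    matrix: OccupancyMatrix,
    kind: str,
    reference_sample: str,
) -> str:
    """The gene's ``kind`` region (promoter/gene_body) with maximal RPM.

    Picks the row with the highest RPM in the reference sample among the
    gene's regions of the requested kind; exact ties go to the 5'-most
    (smallest start) region.
    """
    if matrix.regions is None:
        raise ValueError("matrix carries no region annotation")
    gid = gene.gene_id if isinstance(gene, GeneModel) else gene
    sub = matrix.regions[(matrix.regions["gene_id"] == gid) & (matrix.regions["kind"] == kind)]
    if sub.empty:
        raise KeyError(f"gene {gid!r} has no {kind!r} region in the matrix")
    rpm = matrix.values.loc[sub["region_id"], reference_sample]
    best = rpm.max()
    winners = sub[rpm.to_numpy() == best].sort_values("start")
    return str(winners.iloc[0]["region_id"])


__all__ = [
    "SampleMeta",
    "Coverage",
    "ArrayCoverage",
    "BedGraphCoverage",
    "BigWigCoverage",
    "count_reads",
    "normalize_depth",
    "depth_ratio",
    "OccupancyMatrix",
    "replicate_concordance",
    "majority_direction",
    "strongest_region_for_gene",
]
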