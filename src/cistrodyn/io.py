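"""Readers and writers for the standard formats the pipeline touches.

Reads narrowPeak, BED6 (+ optional summit column), BED12 gene models, GTF,
FASTA and chrom.sizes; writes BED6. BED-family coordinates pass through
unchanged (already 0-based half-open); GTF is converted from 1-based closed
on read.
"""

from __future__ import annotations

import os
from collections.abc import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GeneModel, GenomeModel, GenomicInterval, Peak, PeakSet, ValidationError

NARROWPEAK_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signalValue", "pValue", "qValue", "summit",
]


class PeakParseError(ValueError):
    """A peak file line could not be parsed; carries the 1-based line number."""


def read_chrom_sizes(path: str | os.PathLike) -> GenomeModel:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], comment="#")
    return GenomeModel(zip(df["chrom"].astype(str), df["size"].astype(int)))


def _peak_from_row(row, line_no: int, fmt: str) -> Peak:
    try:
        chrom = str(row["chrom"])
        start, end = int(row["start"]), int(row["end"])
        strand = str(row.get("strand", "."))
        if strand not in ("+", "-"):
            strand = "."
        iv = GenomicInterval(chrom, start, end, strand)
        score = float(row.get("signalValue", row.get("score", 0.0)) or 0.0)
        summit = int(row["summit"]) if "summit" in row and pd.notna(row["summit"]) else -1
    except ValidationError:
        raise
    except Exception as exc:
        raise PeakParseError(f"line {line_no}: cannot parse {fmt} fields ({exc})") from exc
    if summit < 0:
        summit = (end - start) // 2  # summit-less records default to the midpoint
    if summit >= end - start:
        raise PeakParseError(f"line {line_no}: summit offset {summit} outside interval")
    return Peak(iv, summit, score, name=str(row.get("name", ".")))


def read_peaks(
    path: str | os.PathLike,
    fmt: str = "narrowPeak",
    genome: GenomeModel | None = None,
    factor: str = "",
    timepoint: float | None = None,
    replicate: str = "",
) -> PeakSet:
    """Read a peak file into a :class:`PeakSet`.

    ``fmt`` is ``"narrowPeak"`` (10 columns, column 10 = 0-based summit
    offset, -1 meaning unknown) or ``"bed"`` (BED6, with an optional 7th
    summit column). Malformed lines raise :class:`PeakParseError` naming
    the line; out-of-bounds intervals raise ``ValidationError`` when a
    genome is supplied.
    """
    if fmt == "narrowPeak":
        names = NARROWPEAK_COLS
    elif fmt == "bed":
        names = ["chrom", "start", "end", "name", "score", "strand", "summit"]
    else:
        raise ValueError(f"unknown peak format {fmt!r}")
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, names=names, comment="#",
            dtype=str, engine="python",
        )
    except Exception as exc:
        raise PeakParseError(f"cannot read {path}: {exc}") from exc
    peaks = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            peaks.append(_peak_from_row(row, i, fmt))
        except ValidationError as exc:
            raise ValidationError(f"line {i}: {exc}") from exc
    ps = PeakSet(peaks, factor=factor, timepoint=timepoint, replicate=replicate, genome=genome)
    return ps


def write_bed6(peaks: PeakSet, path: str | os.PathLike) -> None:
    """Write peaks as BED6 (name/score/strand from the peak records)."""
    rows = [
        (p.chrom, p.interval.start, p.interval.end, p.name, p.score, p.interval.strand)
        for p in peaks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_narrowpeak(peaks: PeakSet, path: str | os.PathLike) -> None:
    rows = [
        (p.chrom, p.interval.start, p.interval.end, p.name, 0, p.interval.strand,
         p.score, -1, -1, p.summit)
        for p in peaks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_bed12_genes(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from BED12: one line per transcript, grouped by name.

    TSS = start for ``+``/unstranded transcripts, ``end - 1`` for ``-``.
    """
    cols = ["chrom", "start", "end", "name", "score", "strand",
            "thickStart", "thickEnd", "rgb", "blockCount", "blockSizes", "blockStarts"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    genes: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        g = genes.setdefault(row.name, {"chrom": row.chrom, "strand": row.strand,
                                        "tss": [], "bodies": []})
        tss = int(row.start) if row.strand != "-" else int(row.end) - 1
        g["tss"].append(tss)
        g["bodies"].append((int(row.start), int(row.end)))
    return [
        GeneModel(gid, g["chrom"], g["strand"], tuple(g["tss"]), tuple(g["bodies"]))
        for gid, g in genes.items()
    ]


def write_bed12_genes(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    rows = []
    for g in genes:
        for tss, (start, end) in zip(g.tss, g.bodies):
            rows.append((g.chrom, start, end, g.gene_id, 0, g.strand,
                         start, end, "0,0,0", 1, end - start, 0))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_gtf_genes(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from GTF transcript records (1-based -> 0-based)."""
    import pyranges as pr

    gr = pr.read_gtf(str(path))
    df = gr.df if hasattr(gr, "df") else pd.DataFrame(gr)
    df = df[df["Feature"] == "transcript"]
    genes: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        gid = getattr(row, "gene_id")
        start, end = int(row.Start), int(row.End)  # pyranges already 0-based half-open
        g = genes.setdefault(gid, {"chrom": str(row.Chromosome), "strand": str(row.Strand),
                                   "tss": [], "bodies": []})
        g["tss"].append(start if g["strand"] != "-" else end - 1)
        g["bodies"].append((start, end))
    return [
        GeneModel(gid, g["chrom"], g["strand"], tuple(g["tss"]), tuple(g["bodies"]))
        for gid, g in genes.items()
    ]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into a name -> sequence dict (uppercased)."""
    with open(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def extract_sequences(genome_seqs: dict[str, str], intervals: Iterable[GenomicInterval]) -> list[str]:
    """Extract (plus-strand) sequences for intervals from in-memory FASTA."""
    out = []
    for iv in intervals:
        if iv.chrom not in genome_seqs:
            raise KeyError(f"chromosome {iv.chrom!r} absent from genome FASTA")
        out.append(genome_seqs[iv.chrom][iv.start:iv.end])
    return out


__all__ = [
    "PeakParseError",
    "read_chrom_sizes",
    "read_peaks",
    "write_bed6",
    "write_narrowpeak",
    "read_bed12_genes",
    "write_bed12_genes",
    "read_gtf_genes",
    "read_fasta",
    "write_fasta",
    "extract_sequences",
]
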