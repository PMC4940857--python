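"""Responsive-gene filtering and cross-treatment overlap/concordance tests.

Fold changes are stored on the signed linear scale: +2 means two-fold up,
-2 two-fold down ("fold change cutoff +/-2"). A gene is responsive when
|fold| >= cutoff (inclusive) and adjusted p < cutoff (strict). Overlap
between two treatments is scored as concordant (same direction) or
discordant, with a hypergeometric upper-tail test for the overlap size.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLS = ("gene_id", "fold_change", "padj")


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (printed-table convention)."""
    scale = 10 ** decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def signed_fold_from_log2(lfc: float) -> float:
    """log2 fold change -> signed linear fold (lfc=1 -> +2, lfc=-1 -> -2)."""
    return 2.0 ** lfc if lfc >= 0 else -(2.0 ** (-lfc))


def read_de_table(path: str | os.PathLike, log2: bool = False) -> pd.DataFrame:
    """Read a differential-expression TSV (gene_id, fold_change|log2fc, padj[, rpkm])."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if log2 or ("log2fc" in df.columns and "fold_change" not in df.columns):
        df["fold_change"] = df["log2fc"].map(signed_fold_from_log2)
    missing = [c for c in REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"DE table missing columns: {missing}")
    return df


def _validate(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"DE table missing columns: {missing}")


@dataclass(frozen=True)
class GeneSet:
    direction: str  # up / down / all
    p_cut: float
    fc_cut: float
    members: frozenset

    def __len__(self) -> int:
        return len(self.members)


def filter_responsive(
    table: pd.DataFrame,
    p_cut: float = 0.01,
    fc_cut: float = 2.0,
    direction: str = "all",
) -> GeneSet:
    """Genes passing adjusted-p (strict) and signed-fold (inclusive) cutoffs."""
    _validate(table)
    if fc_cut < 1:
        raise ValueError("fc_cut must be >= 1")
    if direction not in ("up", "down", "all"):
        raise ValueError(f"invalid direction {direction!r}")
    sig = table["padj"] < p_cut
    up = sig & (table["fold_change"] >= fc_cut)
    down = sig & (table["fold_change"] <= -fc_cut)
    mask = {"up": up, "down": down, "all": up | down}[direction]
    return GeneSet(direction, p_cut, fc_cut, frozenset(table.loc[mask, "gene_id"]))


def responsive_counts(table: pd.DataFrame, p_cut: float = 0.01, fc_cut: float = 2.0) -> tuple[int, int]:
    """(n up-regulated, n down-regulated) at the given cutoffs."""
    return (
        len(filter_responsive(table, p_cut, fc_cut, "up")),
        len(filter_responsive(table, p_cut, fc_cut, "down")),
    )


def high_confidence_intersection(a: GeneSet, b: GeneSet) -> GeneSet:
    """Genes passing cutoffs in both treatments (same direction/cutoffs)."""
    if a.direction != b.direction:
        raise ValueError("gene sets have different directions")
    if (a.p_cut, a.fc_cut) != (b.p_cut, b.fc_cut):
        raise ValueError("gene sets filtered at different cutoffs")
    return GeneSet(a.direction, a.p_cut, a.fc_cut, a.members & b.members)


def hypergeom_overlap_p(overlap: int, n_a: int, n_b: int, universe: int) -> float:
    """Upper-tail P(X >= overlap) drawing n_b genes from a universe with n_a marked."""
    if universe < max(n_a, n_b):
        raise ValueError("universe smaller than a gene set")
    return float(stats.hypergeom.sf(overlap - 1, universe, n_a, n_b))


def percent_concordant(concordant: int, discordant: int) -> float:
    """100 * concordant / (concordant + discordant), half away from zero, 1 dp."""
    overlap = concordant + discordant
    if overlap == 0:
        raise ValueError("empty overlap")
    return round_half_away(100.0 * concordant / overlap, 1)


@dataclass(frozen=True)
class ConcordanceResult:
    overlap: int
    concordant: int
    discordant: int
    percent_concordant: float
    hypergeom_p: float
    universe: int
    overlap_percent: float | None = None  # overlap relative to the reference set


def overlap_concordance(
    a: pd.DataFrame,
    b: pd.DataFrame,
    p_cut: float = 0.01,
    fc_cut: float = 2.0,
    universe: int | None = None,
) -> ConcordanceResult:
    """Cross-treatment overlap of responsive genes with directional concordance.

    Overlap counts genes responsive (either direction) in both tables;
    concordant = matching fold-change sign, discordant = opposite.
    The hypergeometric universe defaults to the number of genes tested in
    both tables.
    """
    _validate(a)
    _validate(b)
    set_a = filter_responsive(a, p_cut, fc_cut, "all").members
    set_b = filter_responsive(b, p_cut, fc_cut, "all").members
    shared = set_a & set_b
    if universe is None:
        universe = len(set(a["gene_id"]) & set(b["gene_id"]))
    if universe < len(set_a | set_b):
        raise ValueError("universe smaller than the union of responsive sets")
    sign_a = a.set_index("gene_id")["fold_change"]
    sign_b = b.set_index("gene_id")["fold_change"]
    concordant = sum(1 for g in shared if np.sign(sign_a[g]) == np.sign(sign_b[g]))
    discordant = len(shared) - concordant
    pct = percent_concordant(concordant, discordant) if shared else float("nan")
    p = hypergeom_overlap_p(len(shared), len(set_a), len(set_b), universe)
    ov_pct = round_half_away(100.0 * len(shared) / len(set_a), 1) if set_a else None
    return ConcordanceResult(len(shared), concordant, discordant, pct, p, universe, ov_pct)


__all__ = [
    "GeneSet",
    "ConcordanceResult",
    "read_de_table",
    "signed_fold_from_log2",
    "filter_responsive",
    "responsive_counts",
    "high_confidence_intersection",
    "hypergeom_overlap_p",
    "percent_concordant",
    "overlap_concordance",
    "round_half_away",
]
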