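"""PWM scanning and motif fold-enrichment against a scrambled-sequence null.

Fold enrichment follows the shuffled-null recipe: count motif hits across a
set of binding-site sequences, re-count after scrambling every sequence
(composition-preserving), and report observed / mean-null. The scramble is
a mononucleotide permutation by default; a dinucleotide-preserving shuffle
(Altschul-Erickson) is available for GC/CpG-sensitive motifs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np

from .core import PeakSet

_BASES = "ACGT"
_ENC = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_ENC[ord("N")] = 4
_ENC[ord("n")] = 4

NULL_FLOOR = 0.5  # denominator floor for fold = observed / null mean


class PWM:
    """Position probability matrix over {A,C,G,T} with background frequencies."""

    def __init__(self, probs: np.ndarray, background: Sequence[float] | None = None,
                 name: str = "motif"):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 4:
            raise ValueError("PWM must be (L, 4) with L >= 4")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        bg = np.asarray(background if background is not None else [0.25] * 4, dtype=float)
        if not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        self.probs = probs
        self.background = bg
        self.name = name
        # log2 odds; probabilities floored so a zero cell scores very low, not -inf
        self.log_odds = np.log2(np.maximum(probs, 1e-9) / bg)

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def max_score(self) -> float:
        """Best achievable log-odds score (bits)."""
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=1))

    def sample_site(self, rng: np.random.Generator) -> str:
        """Draw one site from the per-position base distributions."""
        idx = [rng.choice(4, p=col / col.sum()) for col in self.probs]
        return "".join(_BASES[i] for i in idx)

    def default_threshold(self, fraction: float = 0.6) -> float:
        return fraction * self.max_score

    @classmethod
    def from_counts(cls, counts: np.ndarray, pseudocount: float = 0.5,
                    background: Sequence[float] | None = None, name: str = "motif") -> "PWM":
        c = np.asarray(counts, dtype=float) + pseudocount
        return cls(c / c.sum(axis=1, keepdims=True), background, name)

    @classmethod
    def from_jaspar(cls, path, pseudocount: float = 0.5) -> "PWM":
        """Read a JASPAR-format count matrix via Bio.motifs."""
        from Bio import motifs

        with open(path) as fh:
            m = motifs.read(fh, "jaspar")
        counts = np.array([[m.counts[b][i] for b in _BASES] for i in range(m.length)])
        return cls.from_counts(counts, pseudocount=pseudocount, name=m.name or "motif")


def consensus_pwm(consensus: str, major_prob: float = 0.85, name: str = "motif") -> PWM:
    """A PWM concentrated on a consensus string (remaining mass split evenly)."""
    probs = np.full((len(consensus), 4), (1 - major_prob) / 3)
    for i, b in enumerate(consensus.upper()):
        probs[i, _BASES.index(b)] = major_prob
    return PWM(probs, name=name)


def _encode(seq: str) -> np.ndarray:
    enc = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if np.any(enc < 0):
        bad = seq[int(np.argmax(enc < 0))]
        raise ValueError(f"invalid sequence character {bad!r}")
    return enc


def _window_scores(enc: np.ndarray, score: np.ndarray) -> np.ndarray:
    """Log-odds score of every window; windows containing N score -inf."""
    L = score.shape[0]
    n_win = enc.size - L + 1
    if n_win <= 0:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(enc, L)
    s = score[np.arange(L)[None, :], np.minimum(win, 3)].sum(axis=1)
    has_n = (win == 4).any(axis=1)
    return np.where(has_n, -np.inf, s)


def scan_pwm(seq: str, pwm: PWM, threshold: float | None = None) -> int:
    """Count windows scoring >= threshold on either strand.

    A window that passes on both strands counts once. ``threshold`` is in
    log2-odds bits; default 60 % of the PWM's maximum achievable score.
    """
    if threshold is None:
        threshold = pwm.default_threshold()
    enc = _encode(seq)
    if enc.size < len(pwm):
        raise ValueError("sequence shorter than the PWM")
    fwd = _window_scores(enc, pwm.log_odds)
    rc = np.where(enc == 4, 4, 3 - enc)[::-1]
    rev = _window_scores(rc, pwm.log_odds)[::-1]  # align window i on both strands
    return int(((fwd >= threshold) | (rev >= threshold)).sum())


def scramble_sequence(seq: str, seed: int | np.random.Generator) -> str:
    """Uniform random permutation of the characters (mononucleotide shuffle)."""
    if not seq:
        raise ValueError("empty sequence")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chars = np.array(list(seq))
    return "".join(chars[rng.permutation(chars.size)])


def dinucleotide_shuffle(seq: str, seed: int | np.random.Generator) -> str:
    """Doublet-preserving shuffle (Altschul-Erickson Eulerian-path method)."""
    if not seq:
        raise ValueError("empty sequence")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(seq) < 3:
        return seq
    verts = sorted(set(seq))
    edges = {v: [] for v in verts}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    # choose last edges forming an arborescence into the final vertex
    for _ in range(10_000):
        last_edge = {}
        ok = True
        for v in verts:
            if v == last:
                continue
            if not edges[v]:
                ok = False
                break
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        if not ok:
            break
        if ok and all(_reaches(v, last, last_edge) for v in verts if v != last):
            pools = {}
            for v in verts:
                pool = list(edges[v])
                if v in last_edge:
                    pool.remove(last_edge[v])
                rng.shuffle(pool)
                if v in last_edge:
                    pool.append(last_edge[v])
                pools[v] = pool
            out = [seq[0]]
            cur = seq[0]
            while pools[cur]:
                nxt = pools[cur].pop(0)
                out.append(nxt)
                cur = nxt
            if len(out) == len(seq):
                return "".join(out)
    return scramble_sequence(seq, rng)  # degenerate composition fallback


def _reaches(v: str, target: str, last_edge: dict) -> bool:
    seen = set()
    while v != target:
        if v in seen or v not in last_edge:
            return False
        seen.add(v)
        v = last_edge[v]
    return True


@dataclass(frozen=True)
class MotifEnrichmentResult:
    observed: int
    null_mean: float
    fold: float
    n_scrambles: int
    seed: int


def motif_fold_enrichment(
    sites: Sequence[str],
    pwm: PWM,
    threshold: float | None = None,
    n_scrambles: int = 10,
    seed: int = 0,
    shuffle: str = "mono",
) -> MotifEnrichmentResult:
    """Observed hit total over site sequences vs the scrambled-sequence null.

    fold = observed / max(mean null hits, 0.5); the floor keeps a fully
    motif-free null from dividing by zero.
    """
    if not sites:
        raise ValueError("need at least one site sequence")
    if n_scrambles < 1:
        raise ValueError("n_scrambles must be >= 1")
    shuf = {"mono": scramble_sequence, "di": dinucleotide_shuffle}[shuffle]
    if threshold is None:
        threshold = pwm.default_threshold()
    observed = sum(scan_pwm(s, pwm, threshold) for s in sites)
    rng = np.random.default_rng(seed)
    null_totals = []
    for _ in range(n_scrambles):
        null_totals.append(sum(scan_pwm(shuf(s, rng), pwm, threshold) for s in sites))
    null_mean = float(np.mean(null_totals))
    fold = observed / max(null_mean, NULL_FLOOR)
    return MotifEnrichmentResult(observed, null_mean, fold, n_scrambles, seed)


def top_enriched_sites(peaks: PeakSet, n: int = 500) -> PeakSet:
    """The ``n`` highest-scoring peaks; score ties break by coordinate."""
    if n > len(peaks):
        warnings.warn(f"requested {n} sites from a set of {len(peaks)}; returning all")
        n = len(peaks)
    ordered = sorted(
        peaks,
        key=lambda p: (-p.score, p.chrom, p.interval.start, p.interval.end),
    )
    return peaks.with_peaks(ordered[:n])


__all__ = [
    "PWM",
    "consensus_pwm",
    "scan_pwm",
    "scramble_sequence",
    "dinucleotide_shuffle",
    "MotifEnrichmentResult",
    "motif_fold_enrichment",
    "top_enriched_sites",
    "NULL_FLOOR",
]
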