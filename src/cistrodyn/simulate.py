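"""Seeded synthetic-data generators for every input the pipeline consumes.

The generators emulate the study design the analysis assumes: replicate
binding-site occupancy at an early and a late time point with planted
gained/lost/stable site classes and negative-binomial counts; 100-bp site
sequences with planted motif occurrences; differential-expression tables
in which repressed genes preferentially lie near planted binding sites;
and a promoter/gene-body scenario in which paused genes gain promoter
RNAP2 while losing gene-body H3K36me3. Every generator is a pure function
of (config, seed): identical inputs give identical outputs, and truth
tables are emitted so downstream calls can be scored without re-deriving
labels.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .core import GeneModel, GenomeModel, GenomicInterval, Peak, PeakSet
from .motifs import PWM

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the emulated conditions."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 5_000_000
    n_genes: int = 500
    n_sites: int = 2_000
    site_width: int = 200
    n_replicates: int = 2
    timepoints: tuple[float, float] = (2.0, 48.0)
    total_aligned_reads: int = 10_000_000
    nb_mean: float = 200.0  # mean early-timepoint site count
    nb_dispersion: float = 0.05  # biological CV of site intensity (edgeR-style BCV)
    site_mean_log_sd: float = 0.5  # lognormal spread of per-site base means
    effect_size: float = 4.0  # mean multiplier for gained (divider for lost) sites
    gained_fraction: float = 0.2
    lost_fraction: float = 0.2
    up_fraction: float = 0.15  # responsive-gene fractions
    down_fraction: float = 0.15
    fc_effect: float = 4.0  # linear fold-change magnitude of responsive genes
    motif_insertion_rate: float = 0.8
    seq_length: int = 100
    proximity_fraction: float = 0.8  # down genes given a site < 10 kb from a TSS
    proximity_max_bp: int = 8_000
    shared_fraction: float = 0.5  # responsive genes also responsive to treatment B
    concordant_fraction: float = 0.7  # shared genes keeping the same direction in B
    pausing_fraction: float = 0.5  # repressed genes planted as paused (rest degraded)
    pausing_n_genes: int = 200
    pausing_effect_log2: float = 1.5
    pausing_noise_sd: float = 0.2

    def __post_init__(self) -> None:
        for name in ("gained_fraction", "lost_fraction", "up_fraction",
                     "down_fraction", "motif_insertion_rate",
                     "proximity_fraction", "pausing_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.gained_fraction + self.lost_fraction > 1:
            raise ValueError("gained + lost fractions exceed 1")
        if self.up_fraction + self.down_fraction > 1:
            raise ValueError("up + down fractions exceed 1")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))

    def to_dict(self) -> dict:
        return asdict(self)


def _chrom_names(config: SimulationConfig) -> list[str]:
    return [f"chr{i + 1}" for i in range(config.n_chromosomes)]


def make_genome_and_genes(
    config: SimulationConfig,
    with_sequence: bool = True,
) -> tuple[GenomeModel, list[GeneModel], dict[str, str]]:
    """Genome sizes, non-overlapping genes (1-3 TSSs each), and FASTA sequences.

    ``with_sequence=False`` skips base-level sequence generation (the gene
    layout is identical either way) for stages that only need coordinates.
    """
    rng = config.rng(1)
    genome = GenomeModel({c: config.chromosome_length for c in _chrom_names(config)})
    seqs = {}
    if with_sequence:
        seqs = {
            c: "".join(rng.choice(_BASES, size=config.chromosome_length))
            for c in genome
        }
    rng = config.rng(11)  # gene layout independent of sequence draw
    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    slot = config.chromosome_length // (per_chrom + 1)
    if slot < 12_000:
        raise ValueError("genes cannot fit on the configured genome")
    genes: list[GeneModel] = []
    gi = 0
    for chrom in genome:
        for k in range(per_chrom):
            if gi >= config.n_genes:
                break
            anchor = (k + 1) * slot
            length = int(rng.integers(2_000, 10_000))
            strand = "+" if rng.random() < 0.5 else "-"
            n_tss = int(rng.integers(1, 4))
            offsets = [0] + sorted(rng.integers(100, 1_000, size=n_tss - 1).tolist())
            start, end = anchor, anchor + length
            tss, bodies = [], []
            for off in offsets:
                if strand == "+":
                    tss.append(start + off)
                    bodies.append((start + off, end))
                else:
                    tss.append(end - 1 - off)
                    bodies.append((start, end - off))
            genes.append(GeneModel(f"g{gi:04d}", chrom, strand, tuple(tss), tuple(bodies)))
            gi += 1
    return genome, genes, seqs


def _random_sites(
    config: SimulationConfig,
    genome: GenomeModel,
    rng: np.random.Generator,
    n: int,
) -> list[Peak]:
    chroms = list(genome)
    peaks = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, genome[chrom] - config.site_width))
        iv = GenomicInterval(chrom, start, start + config.site_width)
        summit = int(rng.integers(config.site_width // 4, 3 * config.site_width // 4))
        peaks.append(Peak(iv, summit, score=float(rng.uniform(1, 100)), name=f"s{i:05d}"))
    return peaks


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts, gamma-Poisson mixed.

    ``dispersion`` is the biological coefficient of variation of the
    latent site intensity (the square root of the edgeR-style dispersion):
    var = mean + (dispersion * mean)^2, so the count CV approaches
    ``dispersion`` at high means.
    """
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion ** 2
    p = r / (r + np.asarray(mean, dtype=float))
    return rng.negative_binomial(r, p)


def simulate_occupancy(
    config: SimulationConfig,
    genome: GenomeModel,
) -> dict:
    """Planted temporal occupancy: peaks, replicate counts, sample metadata, truth.

    Site base means are lognormal around ``nb_mean``; gained sites have the
    late-timepoint mean multiplied by ``effect_size``, lost sites divided,
    stable sites unchanged; counts are negative-binomial per replicate.
    """
    rng = config.rng(2)
    peaks = _random_sites(config, genome, rng, config.n_sites)
    n = len(peaks)
    classes = np.array(["stable"] * n, dtype=object)
    n_g = int(round(config.gained_fraction * n))
    n_l = int(round(config.lost_fraction * n))
    idx = rng.permutation(n)
    classes[idx[:n_g]] = "gained"
    classes[idx[n_g:n_g + n_l]] = "lost"
    base = config.nb_mean * np.exp(rng.normal(0, config.site_mean_log_sd, size=n))
    t_early, t_late = config.timepoints
    late = np.where(
        classes == "gained", base * config.effect_size,
        np.where(classes == "lost", base / config.effect_size, base),
    )
    from .occupancy import SampleMeta

    site_ids = [p.name for p in peaks]
    counts = {}
    samples = {}
    for t, mean in ((t_early, base), (t_late, late)):
        for r in range(config.n_replicates):
            sid = f"tf_{t:g}h_r{r + 1}"
            counts[sid] = _nb_draw(rng, mean, config.nb_dispersion)
            samples[sid] = SampleMeta(sid, "TF", t, f"r{r + 1}", config.total_aligned_reads)
    counts_df = pd.DataFrame(counts, index=pd.Index(site_ids, name="site"))
    truth = pd.DataFrame({"site": site_ids, "class": classes, "base_mean": base}).set_index("site")
    return {
        "peaks": PeakSet(peaks, factor="TF"),
        "counts": counts_df,
        "samples": samples,
        "truth": truth,
        "times": [samples[c].timepoint for c in counts_df.columns],
    }


def simulate_sequences_with_motifs(
    config: SimulationConfig,
    pwm: PWM,
) -> tuple[list[str], pd.DataFrame]:
    """Uniform-composition site sequences with consensus-sampled motif insertions."""
    rng = config.rng(3)
    L = config.seq_length
    if len(pwm) > L:
        raise ValueError("motif longer than the site sequence")
    seqs, rows = [], []
    n = min(config.n_sites, 1_000)
    for i in range(n):
        seq = "".join(rng.choice(_BASES, size=L))
        planted = rng.random() < config.motif_insertion_rate
        pos = -1
        if planted:
            pos = int(rng.integers(0, L - len(pwm) + 1))
            ins = pwm.sample_site(rng)
            seq = seq[:pos] + ins + seq[pos + len(ins):]
        seqs.append(seq)
        rows.append((f"seq{i:05d}", planted, pos))
    truth = pd.DataFrame(rows, columns=["seq_id", "planted", "position"]).set_index("seq_id")
    return seqs, truth


def simulate_expression_with_proximity(
    config: SimulationConfig,
    genes: list[GeneModel],
    sites: PeakSet,
    genome: GenomeModel | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, PeakSet]:
    """DE table with planted up/down genes; down genes enriched near new sites.

    Planted responsive genes always pass the (p < 0.01, |fold| >= 2)
    cutoffs; null genes never pass the fold cutoff. A ``proximity_fraction``
    of down genes receives one extra site planted < 10 kb from a TSS,
    appended to the supplied background sites.
    """
    rng = config.rng(4)
    n = len(genes)
    labels = np.array(["null"] * n, dtype=object)
    n_up = int(round(config.up_fraction * n))
    n_down = int(round(config.down_fraction * n))
    idx = rng.permutation(n)
    labels[idx[:n_up]] = "up"
    labels[idx[n_up:n_up + n_down]] = "down"
    fold = np.empty(n)
    padj = np.empty(n)
    for i, lab in enumerate(labels):
        if lab == "null":
            fold[i] = np.sign(rng.standard_normal()) * 2 ** abs(rng.normal(0, 0.1))
            padj[i] = rng.uniform()
        else:
            mag = max(config.fc_effect * 2 ** rng.normal(0, 0.25), 2.05)
            fold[i] = mag if lab == "up" else -mag
            padj[i] = 10 ** (-rng.uniform(3, 12))
    rpkm = np.exp(rng.normal(2, 1, size=n))
    table = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "fold_change": fold,
        "padj": padj,
        "rpkm": rpkm,
    })
    planted_sites = list(sites.peaks)
    near = np.zeros(n, dtype=bool)
    k = len(planted_sites)
    for i, (g, lab) in enumerate(zip(genes, labels)):
        if lab != "down" or rng.random() >= config.proximity_fraction:
            continue
        tss = int(g.tss[0])
        offset = int(rng.integers(200, config.proximity_max_bp))
        start = max(0, tss + (offset if rng.random() < 0.5 else -offset - config.site_width))
        if genome is not None:
            start = min(start, genome[g.chrom] - config.site_width)
        iv = GenomicInterval(g.chrom, start, start + config.site_width)
        planted_sites.append(Peak(iv, config.site_width // 2, score=50.0, name=f"prox{k:05d}"))
        near[i] = True
        k += 1
    # gene-body elongation-mark log2 ratio: repressed genes with a nearby
    # planted site lose more gene-body signal than site-free repressed genes
    body_ratio = rng.normal(0, 0.3, size=n)
    is_down = labels == "down"
    body_ratio[is_down & near] = rng.normal(-1.0, 0.5, size=int((is_down & near).sum()))
    body_ratio[is_down & ~near] = rng.normal(-0.3, 0.5, size=int((is_down & ~near).sum()))
    truth = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "label": labels,
        "planted_near_site": near,
        "body_ratio": body_ratio,
    }).set_index("gene_id")
    return table, truth, sites.with_peaks(planted_sites)


def simulate_second_treatment(
    config: SimulationConfig,
    table: pd.DataFrame,
    truth: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A second drug's DE table sharing part of the first response.

    Each responsive gene of the first treatment stays responsive with
    probability ``shared_fraction``; shared genes keep their direction
    with probability ``concordant_fraction`` and flip otherwise. All
    other genes are null in the second treatment.
    """
    rng = config.rng(6)
    fold = np.empty(len(table))
    padj = np.empty(len(table))
    labels = np.array(["null"] * len(table), dtype=object)
    for i, gid in enumerate(table["gene_id"]):
        lab = truth.loc[gid, "label"]
        if lab != "null" and rng.random() < config.shared_fraction:
            mag = max(config.fc_effect * 2 ** rng.normal(0, 0.25), 2.05)
            same = rng.random() < config.concordant_fraction
            direction = lab if same else ("down" if lab == "up" else "up")
            fold[i] = mag if direction == "up" else -mag
            padj[i] = 10 ** (-rng.uniform(3, 12))
            labels[i] = direction
        else:
            fold[i] = np.sign(rng.standard_normal()) * 2 ** abs(rng.normal(0, 0.1))
            padj[i] = rng.uniform()
    table_b = pd.DataFrame({
        "gene_id": table["gene_id"],
        "fold_change": fold,
        "padj": padj,
        "rpkm": table["rpkm"],
    })
    truth_b = pd.DataFrame({"gene_id": table["gene_id"], "label": labels}).set_index("gene_id")
    return table_b, truth_b


def simulate_pausing_scenario(config: SimulationConfig) -> pd.DataFrame:
    """Promoter RNAP2 and gene-body H3K36me3 levels for repressed genes.

    Pausing-planted genes gain promoter occupancy (late vs control) while
    losing gene-body signal; degradation-planted genes lose both. Levels
    carry lognormal noise of sd ``pausing_noise_sd`` (log2 units).
    """
    rng = config.rng(5)
    n = config.pausing_n_genes
    n_pause = int(round(config.pausing_fraction * n))
    mech = np.array(["pausing"] * n_pause + ["degradation"] * (n - n_pause), dtype=object)
    rng.shuffle(mech)
    d = config.pausing_effect_log2
    sd = config.pausing_noise_sd
    prom0 = np.exp(rng.normal(np.log(20), 0.4, size=n))
    body0 = np.exp(rng.normal(np.log(20), 0.4, size=n))
    prom_shift = np.where(mech == "pausing", d, -d) + rng.normal(0, sd, size=n)
    body_shift = -d + rng.normal(0, sd, size=n)
    return pd.DataFrame({
        "gene_id": [f"pg{i:04d}" for i in range(n)],
        "prom_rpm_0h": prom0,
        "prom_rpm_48h": prom0 * 2.0 ** prom_shift,
        "body_rpm_0h": body0,
        "body_rpm_48h": body0 * 2.0 ** body_shift,
        "rna_direction": "down",
        "true_mechanism": mech,
    }).set_index("gene_id")


__all__ = [
    "SimulationConfig",
    "make_genome_and_genes",
    "simulate_occupancy",
    "simulate_sequences_with_motifs",
    "simulate_expression_with_proximity",
    "simulate_second_treatment",
    "simulate_pausing_scenario",
]
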