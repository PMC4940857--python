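# cistrodyn

Temporal cistrome dynamics and regulatory integration for nuclear-receptor
ChIP-seq / RNA-seq time courses.

When a ligand-activated transcription factor (a nuclear receptor such as
LXR or PPARG) is switched on by an agonist, its genome-wide binding
program, the chromatin marks around its sites, and the transcriptome all
move on different time scales. `cistrodyn` implements the integration
layer that ties those readouts together for a two-time-point design:

* **Occupancy quantification** — reads are tabulated over 100-bp windows
  centered on peak summits and normalized to library size
  (RPM = count / total aligned reads × 10⁶); condition contrasts are
  log₂ ratios with an additive pseudocount,
  `r = log2((a + c)/(b + c))`.
* **Temporal dynamics** — per site, RPM is regressed on time across
  replicate observations (OLS, slope β, two-sided t-test with
  df = n − 2); sites are *gained* (β > 0, p < α), *lost* (β < 0, p < α)
  or *stable*, and the top 50 % of p-ranked sites per class feed cofactor
  motif analysis.
* **Motif fold-enrichment** — PWM log-odds scanning of site sequences on
  both strands versus a composition-preserving scrambled-sequence null:
  `fold = observed hits / mean(hits over scrambles)`.
* **Responsive-gene concordance** — differential-expression tables are
  filtered at adjusted p < 0.01 with signed linear fold cutoffs of ±2 and
  ±1.5; overlap between two treatments is split into concordant /
  discordant direction, with a hypergeometric upper-tail overlap test.
* **Distance-CDF enrichment** — for each gene, the distance from its TSS
  to the nearest binding-site edge; cumulative fractions over a cutoff
  grid are compared against the all-genes background.
* **Pausing signature** — a repressed gene whose promoter RNAP2 log₂
  ratio rises while its gene-body H3K36me3 ratio falls is
  *pausing-consistent*; promoter-down with body-down is *reduced
  initiation*. Gene-body ratios for genes with a site < 10 kb from the
  promoter versus genes with no site within 100 kb are contrasted by a
  Wilcoxon rank-sum test (exact by enumeration for small groups).

A seeded synthetic-data module generates every input the pipeline
consumes — genome FASTA, gene models, narrowPeak sites, negative-binomial
replicate count tables, site sequences with planted motifs, DE tables in
which repressed genes lie preferentially near planted sites, and a
promoter/gene-body pausing scenario — together with truth labels, so the
whole analysis is testable without any download.

## Worked example

```bash
python examples/motif_enrichment.py
```

```text
insertion rate 0.0: observed   47 hits, null mean   49.8, fold 0.94
insertion rate 0.2: observed   73 hits, null mean   48.1, fold 1.52
insertion rate 0.8: observed  150 hits, null mean   44.9, fold 3.34
```

200 synthetic 100-bp site sequences are scanned with an AP1-style PWM
(consensus TGACTCA). With no planted motif the fold is ~1 (the scrambled
null is calibrated); planting the consensus in 20 % and 80 % of the
sites raises the fold to 1.5 and 3.3 — enrichment tracks the true
insertion rate.

The full pipeline, from simulation through every report table:

```bash
cistrodyn run --seed 0 --outdir cistrodyn_out
# or: python examples/end_to_end.py
```

```text
dynamic-site calls: {'stable': 1151, 'gained': 431, 'lost': 418}
motif fold enrichment at planted sites: 3.20
 fc_cut  up_a  down_a  ...  percent_concordant  overlap_percent
    2.0    75      75  ...                72.2             48.0
repressed-vs-background distance-CDF gap: 0.077
pausing calls: {'reduced_initiation': 100, 'pausing_consistent': 100}
```

2,000 planted sites (20 % gained, 20 % lost) are recovered from the
replicate counts; the concordance table mirrors the two-treatment overlap
arithmetic; the positive CDF gap shows repressed genes sitting closer to
binding sites than background; and all 200 pausing-scenario genes are
classified to their planted mechanism.

Other example scripts: `temporal_dynamics.py`, `concordance_tables.py`,
`distance_enrichment.py`, `pausing_signature.py` — one capability each.

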