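"""Motif fold-enrichment against a scrambled-sequence null.

Generates 100-bp binding-site sequences with an AP1-style consensus
planted in 80% of them, scans with the PWM on both strands, and compares
observed hit totals with composition-preserving scrambles.
"""

from cistrodyn.motifs import consensus_pwm, motif_fold_enrichment
from cistrodyn.simulate import SimulationConfig, simulate_sequences_with_motifs

pwm = consensus_pwm("TGACTCA", name="AP1")

for rate in (0.0, 0.2, 0.8):
    cfg = SimulationConfig(seed=0, motif_insertion_rate=rate, n_sites=200)
    seqs, truth = simulate_sequences_with_motifs(cfg, pwm)
    res = motif_fold_enrichment(seqs, pwm, n_scrambles=10, seed=0)
    print(f"insertion rate {rate:.1f}: observed {res.observed:4d} hits, "
          f"null mean {res.null_mean:6.1f}, fold {res.fold:.2f}")
# Fold ~1 on motif-free sequences (the null is calibrated) and rises
# monotonically with the fraction of sites carrying a planted motif.
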