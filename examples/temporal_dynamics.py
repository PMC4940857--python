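"""Rank temporal occupancy changes at planted binding sites.

Simulates replicate ChIP-seq counts at 2 h and 48 h with known gained /
lost / stable site classes, fits a per-site linear model of RPM on time,
and reports how well the slope + p-value classification recovers truth.
"""

import pandas as pd

from cistrodyn.dynamics import fit_trends, select_top_fraction
from cistrodyn.occupancy import OccupancyMatrix
from cistrodyn.simulate import SimulationConfig, make_genome_and_genes, simulate_occupancy

cfg = SimulationConfig(seed=0)
genome, _, _ = make_genome_and_genes(cfg, with_sequence=False)
occ = simulate_occupancy(cfg, genome)
matrix = OccupancyMatrix.from_counts(occ["counts"], occ["samples"])
trends = fit_trends(matrix.values, occ["times"], alpha=0.05)

truth = occ["truth"]["class"]
print(pd.crosstab(trends["class"].rename("called"), truth.rename("planted")))
for klass in ("gained", "lost"):
    planted = truth[truth == klass].index
    rate = (trends.loc[planted, "class"] == klass).mean()
    print(f"{klass}: {100 * rate:.1f}% of planted sites recovered")
top = select_top_fraction(trends, "gained", 0.5)
print(f"top 50% of p-ranked gained sites for cofactor motif work: {len(top)} sites")
# The crosstab shows called class vs planted class; off-diagonal stable
# counts are sites whose 4-fold shift the df=2 test could not resolve.
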