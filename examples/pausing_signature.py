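"""Classify the repression mechanism of down-regulated genes.

Rising promoter RNAP2 occupancy with falling gene-body H3K36me3 in a gene
whose mRNA falls is the promoter-proximal pausing signature; falling
promoter occupancy indicates reduced initiation instead.
"""

import pandas as pd

from cistrodyn.integration import classify_repression_mechanism
from cistrodyn.occupancy import depth_ratio
from cistrodyn.simulate import SimulationConfig, simulate_pausing_scenario

table = simulate_pausing_scenario(SimulationConfig(seed=0))
calls = []
for gid, row in table.iterrows():
    call = classify_repression_mechanism(
        gid,
        depth_ratio(row["prom_rpm_48h"], row["prom_rpm_0h"]),
        depth_ratio(row["body_rpm_48h"], row["body_rpm_0h"]),
        "down",
    )
    calls.append((gid, call.mechanism, row["true_mechanism"]))
df = pd.DataFrame(calls, columns=["gene", "called", "planted"]).set_index("gene")
print(pd.crosstab(df["called"], df["planted"]))
acc = ((df["planted"] == "pausing") == (df["called"] == "pausing_consistent")).mean()
print(f"mechanism recovery at log2 noise sd 0.2: {100 * acc:.1f}%")
# Every planted paused gene should land in pausing_consistent and every
# degradation gene in reduced_initiation; noise sd 0.2 barely blurs this.
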