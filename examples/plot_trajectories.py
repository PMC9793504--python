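"""Render the standard sequence-analysis graphics for a synthetic cohort.

Writes state-distribution plots (overall and per cluster), an index plot
and sequence-frequency plots under scratch/plots/, each with a companion
CSV of the plotted numbers.
"""

from pathlib import Path

import pandas as pd

import caretraj as ct

out = Path("scratch/plots")
out.mkdir(parents=True, exist_ok=True)

cohort, latent = ct.generate_cohort(ct.default_config(n_raw=800), seed=1)
kept, _, _ = ct.filter_min_observations(cohort)

dm = ct.pairwise_distance_matrix(kept, ct.build_cost_model(kept.specs))
sol = ct.cut(ct.agglomerate(dm, "complete"), 6, dm)

p1 = ct.plot_state_distribution(kept, out / "state_distribution.png")
p2 = ct.plot_state_distribution(kept, out / "state_distribution_by_cluster.png",
                                labels=sol.labels)
paths = ct.plot_index_and_frequency(kept, out / "sequences")

table = pd.read_csv(out / "state_distribution.csv")
dead_w11 = table[(table.channel == "ambulatory") & (table.state == "DEAD")
                 & (table.wave == 11)]["share"].iloc[0]
print(f"wrote {p1}, {p2} and {[str(p) for p in paths]}")
print(f"share dead by wave 11: {100 * dead_w11:.1f}%")
# The stacked bands show utilization levels per wave with the overlay
# states on top; the dead band can only grow across waves.
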