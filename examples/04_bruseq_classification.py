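"""Knockout time-course fold changes and dynamic-response classes.

Plants 100 genes into the five response patterns (sustained induction or
repression, induction or repression reset, dynamic) in a simulated
nascent-RNA count matrix (control guide + two knockout guides at days
0/2/4/8/16), then recomputes fold changes, the dual-guide regulated filter
and the class labels, and picks the cluster count by the WSS elbow.
"""

import numpy as np

from grhl2net.bruseq_response import compute_responses, heatmap_matrix, \
    optimal_cluster_count
from grhl2net.synthetic_data import simulate_bruseq_counts, simulate_genome

genome, _ = simulate_genome(120, {"chr1": 8_000_000}, seed=9)
gids = sorted(genome.annotation.genes)
classes = ("sustained_induction", "sustained_repression", "induction_reset",
           "repression_reset", "dynamic")
assign = {gid: classes[i % 5] for i, gid in enumerate(gids[:100])}
matrix, _ = simulate_bruseq_counts(genome.annotation, assign, seed=10,
                                   dispersion=0.05)

responses = compute_responses(matrix)
recovered = sum(responses.at[g, "response_class"] == c for g, c in assign.items())
print(f"planted genes: {len(assign)}, classes recovered: {recovered} "
      f"({100 * recovered / len(assign):.1f}%)")
print(f"regulated genes (dual-guide filter, control excluded): "
      f"{int(responses['regulated'].sum())}")
print("\nclass counts among regulated genes:")
print(responses.loc[responses["regulated"], "response_class"]
      .value_counts().to_string())

heat = heatmap_matrix(responses)
values = heat[[c for c in heat.columns if c.startswith("log2AFC:")]]
k, wss = optimal_cluster_count(values.to_numpy(), k_max=8, seed=0)
print(f"\nWSS elbow chooses k = {k} clusters "
      f"(WSS curve: {np.round(wss, 1).tolist()})")
print("the induced, repressed and dynamic patterns form the dominant groups; "
      "sustained and reset profiles differ only at day 16, so under noise the "
      "elbow can merge them")
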