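"""Integrate promoter binding with the transcriptional response.

Builds a noise-free scenario with 4 regulated genes whose promoter peaks
are shared across all three cell lines, 8 with a promoter peak in the
reference line only, and 6 regulated genes without promoter binding. The
nested candidate-target sets (conserved <= reference <= regulated) are
recovered exactly: 4 and 12 against 18 regulated genes.
"""

from grhl2net.bruseq_response import compute_responses
from grhl2net.consensus_peaks import intersect_sets
from grhl2net.integration import direct_targets, targets_to_frame
from grhl2net.peak_annotation import annotate_peaks, calls_to_frame
from grhl2net.synthetic_data import simulate_integration_scenario

scenario = simulate_integration_scenario(seed=11)
responses = compute_responses(scenario.counts)
calls = {
    sample: calls_to_frame(annotate_peaks(peaks, scenario.genome.annotation))
    for sample, peaks in scenario.peaksets.items()
}
consensus, _ = intersect_sets(scenario.peaksets)
targets = direct_targets(
    calls, consensus, responses, scenario.reference,
    set(scenario.genome.annotation.genes),
)

frame = targets_to_frame(targets)
print(f"regulated genes                    : {len(frame)}")
print(f"with reference promoter binding    : "
      f"{int(frame['promoter_bound_reference'].sum())}")
print(f"with conserved promoter binding    : "
      f"{int(frame['promoter_bound_conserved'].sum())}")
print("\nfirst candidate targets:")
print(frame.head(6).to_string(index=False))
print("\nconserved-promoter targets are the strongest candidates for direct "
      "regulation at the promoter")
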