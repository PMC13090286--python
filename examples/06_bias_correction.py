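"""Reduce the interval bias from death/subsampling using the lineage trees.

Under subsampling, some cells observed at t_i have no observed descendant at
t_{i+1}, so the pair of reweighted marginals is not compatible with any one
SDE.  The correction cuts the later snapshot's observed trees at t_i,
estimates each surviving branch's state there (Gaussian message passing),
and re-selects the observed t_i cells by transport matching.  We score each
pair by forward-simulating the SDE from the earlier marginal and measuring
the energy distance to the later one (the "interval incompatibility").
"""

import numpy as np

from lineagetraj import (builtin_model, compatible_pair, correct_snapshot,
                         estimate_ancestors, interval_incompatibility,
                         reweighted_measure, simulate_timecourse)

times = np.linspace(1.0, 4.0, 5)
full = builtin_model("shallowwell", q_final=1.0)
sub = builtin_model("shallowwell", q_final=0.05)

rows = {"no subsampling": 0.0, "subsampled, uncorrected": 0.0,
        "subsampled, corrected": 0.0}
snaps_full = simulate_timecourse(full, None, times, 15, seed=4)
snaps_sub = simulate_timecourse(sub, None, times, 15, seed=4)
for i in range(len(times) - 1):
    pair = (reweighted_measure(snaps_full[i]), reweighted_measure(snaps_full[i + 1]))
    rows["no subsampling"] += interval_incompatibility(
        pair, full.drift, full.diffusivity, seed=10 + i, reflect=full.reflect)
    pair = (reweighted_measure(snaps_sub[i]), reweighted_measure(snaps_sub[i + 1]))
    rows["subsampled, uncorrected"] += interval_incompatibility(
        pair, sub.drift, sub.diffusivity, seed=10 + i, reflect=sub.reflect)
    anc = estimate_ancestors(snaps_sub[i + 1], snaps_sub[i].time, sub.diffusivity)
    pair = compatible_pair(correct_snapshot(anc, snaps_sub[i]), snaps_sub[i + 1])
    rows["subsampled, corrected"] += interval_incompatibility(
        pair, sub.drift, sub.diffusivity, seed=10 + i, reflect=sub.reflect)

print("cumulated interval incompatibility (smaller = more compatible pairs):")
for k, v in rows.items():
    print(f"  {k:26s} {v:.3f}")
print("\nthe correction should close most of the gap to the "
      "no-subsampling reference")
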