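"""Let the adaptive loop choose the number of clusters.

The deterministic strategy grows Q by LBG splits and stops once the fused
composition moves by less than eta (in scaled variational distance) between
consecutive Q.  The trace shows the per-Q deltas shrinking until the rule
fires; the final estimate is the one at the stopping Q.
"""

import ark16s as a
from ark16s.io import align_union

sample = a.simulate_sample(a.SimulationConfig(
    M_taxa=30, ref_length=1500, abundance_law="power_law", depth=1500,
    error_rate=0.01, chimera_rate=0.05, family_size=5, seed=7,
))
features = a.featurize(sample.reads, k=6)
reference = a.build_reference(sample.reference, sample.taxonomy, k=6, mode="split")

result = a.adaptive_Q_loop(
    features, reference,
    a.ArkConfig(strategy="deterministic", eta=0.01, Q_max=32, seed=7),
)

truth, estimate = align_union(sample.truth, result.estimate)
print(f"stopped at Q = {result.Q_used} (eta = 0.01, Q_max = 32)")
print("scaled-VD deltas per Q:",
      " ".join(f"{d:.4f}" for d in result.trace))
print(f"VD at stopping Q: {a.variational_distance(truth, estimate):.4f}")
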