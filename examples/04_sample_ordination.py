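"""Compare many estimated profiles by Jensen-Shannon divergence + PCoA.

Simulates two groups of samples with different dominant taxa, estimates
each composition, and ordinates the estimates.  Samples from the same
group should fall close together along the first principal coordinate.
"""

import numpy as np

import ark16s as a
from ark16s.metrics import js_distance_matrix

records, taxonomy = a.make_reference(12, length=1200, seed=0)
reference = a.build_reference(records, taxonomy, k=6, mode="whole")

profiles, labels = [], []
for group, bias in (("A", 0), ("B", 6)):
    for rep in range(4):
        truth = np.full(12, 0.02)
        truth[bias : bias + 3] = [0.5, 0.3, 0.14]
        truth /= truth.sum()
        cfg = a.SimulationConfig(M_taxa=12, ref_length=1200, depth=1500,
                                 seed=100 * (bias + 1) + rep)
        sample = a.simulate_reads(records, taxonomy, truth, cfg)
        feats = a.featurize(sample.reads, 6)
        result = a.ark_estimate(feats, reference,
                                a.ArkConfig(strategy="random", Q=8, seed=rep))
        profiles.append(result.estimate)
        labels.append(group)

D = js_distance_matrix(profiles)
coords, explained = a.pcoa(D, dims=2)
print(f"axis 1 explains {explained[0]:.1%}, axis 2 {explained[1]:.1%}")
for label, (x, y) in zip(labels, coords):
    print(f"  group {label}: PC1 = {x:+.3f}, PC2 = {y:+.3f}")
print("same-group samples share the sign of PC1:",
      len({np.sign(x) for (x, _), l in zip(coords, labels) if l == 'A'}) == 1)
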