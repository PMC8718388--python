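"""Locate and classify all equilibria for one parameter set.

The model always has the extinction state E0=(0,0) (a saddle) and the
prey-only state E1=(1,0) (a stable node: the Allee effect is strong, so a
rare predator always dies out).  Whether the species can coexist depends
on the interior nullcline intersections.
"""

from alleepred import (ModelParams, boundary_equilibria,
                       find_interior_equilibria, make_allee)

p = ModelParams(alpha=1.8, beta=0.8, m=0.5)
h = make_allee("monod", delta=0.1)

print(f"alpha={p.alpha}, beta={p.beta}, m={p.m}, Monod delta={h.delta}\n")
for eq in list(boundary_equilibria(p)) + find_interior_equilibria(p, h):
    ev = ", ".join(f"{e:.4f}" for e in eq.eigenvalues)
    print(f"{eq.kind:8s} at ({eq.x:.4f}, {eq.y:.4f})  "
          f"{eq.topo_type:6s} {eq.stability:8s}  eigenvalues: {ev}")

print("\nThe smaller-x interior point (E1star) is the coexistence state: a")
print("focus that can be stable or unstable.  The larger-x point (E2star)")
print("is always a saddle; its stable manifold bounds the coexistence basin.")
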