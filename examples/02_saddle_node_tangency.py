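"""Saddle-node bifurcation: the Allee intensity beyond which coexistence
is impossible.

As delta grows the predator nullcline sweeps right and the two interior
equilibria collide and vanish where the nullclines become tangent.  The
tangency is located by solving the two nullcline equations together with
the equal-slope condition (det J = 0).
"""

from alleepred import find_interior_equilibria, find_saddle_node, \
    make_allee, ModelParams

params = {"alpha": 1.8, "beta": 0.8, "m": 0.5, "delta": 0.25}
sn = find_saddle_node(params, free="delta", bracket=(0.1, 0.4))

d_sn = sn.params["delta"]
print(f"tangency at delta_SN = {d_sn:.6f}, equilibrium ({sn.x:.4f}, {sn.y:.4f})")
print(f"  det J = {sn.aux['det']:.2e} (zero at the fold)")
print(f"  transversality w.D2F(v,v) = {sn.aux['w_D2F_vv']:.4f} "
      f"(negative for every admissible Allee function)")

p = ModelParams(params["alpha"], params["beta"], params["m"])
for d in (0.9 * d_sn, 1.1 * d_sn):
    n = len(find_interior_equilibria(p, make_allee("monod", d)))
    print(f"delta = {d:.4f}: {n} interior equilibria")
print("\nBelow delta_SN the species can coexist; above it the predator is")
print("doomed regardless of its initial density.")
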