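"""Compose a 9-block arterial tree from deformed reference building blocks.

Builds the block library (tubes T1/T2/T3 and the symmetric bifurcation B),
deforms a tube analytically, then assembles a tree of 4 trunk tubes, one
bifurcation and two 2-tube branches.  Prints the interface bookkeeping that
the coupled solver relies on.
"""

import numpy as np

from rbeflow import (DeformationParams, apply_deformation, build_reference_block,
                     build_tree, nonaffine_map)

# one deformed tube: 30% longer, outlet tapered to 80%, bent by 0.3 rad
block = build_reference_block("T2", resolution=6)
gmap = nonaffine_map(block, DeformationParams(
    {"length_ratio": 1.3, "radius_ratio": 0.8, "bend_angle": 0.3}))
sd = apply_deformation(block, gmap)
out = sd.interfaces["outlet"]
print(f"deformed T2 outlet: centre {np.round(out.center, 3)}, "
      f"normal {np.round(out.normal, 3)}, half-width {out.halfwidth:.3f}")
print("  (half-width = 0.8 x 0.5: the taper acts on the outlet only)")

# the 9-subdomain tree: 4 trunk tubes + bifurcation + 2 tubes per branch
tree = build_tree(["T1", "T2", "T1", "T3"], (["T1", "T2"], ["T1", "T2"]),
                  resolution=5)
print(f"\ntree: {tree.n_subdomains} subdomains, {len(tree.internal)} internal "
      f"interfaces, {len(tree.inlets)} inlet, {len(tree.outlets)} outlets")
print("  (a tree of N blocks always has N - 1 internal interfaces)")
for j, sd in enumerate(tree.subdomains):
    print(f"  subdomain {j}: kind {sd.kind}, neighbours {sorted(tree.neighbours(j))}")
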