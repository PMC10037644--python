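"""Q-matrix SAR bookkeeping: point SAR, 10 g averaging, VOP compression.

SAR for a drive u is the quadratic form u^H Q(r) u; the regulated local
quantity is the maximum after exact 10 g mass averaging.  VOPs compress
~5e4 averaged matrices into a handful of dominating ones with a certified
overestimation bound, cheap enough to sit inside an optimization loop.
"""

import numpy as np

import ptxshim as px
from ptxshim import sar

scene = px.build_scene()
total = px.compute_fields(scene)["total"]

q = sar.point_q_matrices(total, scene.sigma, scene.rho, scene.phantom_mask)
q10 = sar.average_q_10g(q, scene.rho, scene.grid)
vops = sar.compress_vops(q10, epsilon=0.05)
print(f"{len(q)} point Q-matrices -> {len(vops)} VOPs "
      f"(epsilon = {vops.epsilon}, bound = {vops.overestimation_bound:.3g} W/kg)")

u = px.cp_vector(total.n_channels).u
exact = sar.eval_sar(u, q10).max_value
bound = sar.eval_sar(u, vops).max_value
print(f"CP-mode SAR10g,max at 1 W forward: exact {exact:.3f} W/kg, "
      f"VOP bound {bound:.3f} W/kg")
# The VOP value can only overestimate — never underestimate — the exact max,
# so any drive certified safe through the VOPs is safe against the full set.

scaled = px.scale_to_limit(px.cp_vector(total.n_channels), q10, sar_limit=20.0)
print(f"scale K bringing CP to the 20 W/kg local limit: {scaled.K:.2f} "
      f"(total forward power {scaled.total_power:.1f} W)")
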