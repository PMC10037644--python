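"""How implant orientation changes the RF coupling under the CP drive.

Rotating the wire away from B0 reduces the tangential E-field that
drives current onto it: coupling is maximal for the pose parallel to B0
and essentially vanishes for the transverse, tangential pose
(theta = 90, phi = 0).  A coarser 10 mm grid keeps this example quick.
"""

from ptxshim.metrics import implant_current_sweep

df = implant_current_sweep({"grid": {"spacing_mm": 10.0}})
print(df.to_string(index=False))
best = df.loc[df.current_norm.idxmin()]
print(f"\nleast-coupled orientation: theta={best.theta:.0f}, phi={best.phi:.0f}"
      " — the pose with the smallest implant artefact and tip heating")
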