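# ptxshim

Implant-aware parallel-transmit (pTx) B1+ shimming with local-SAR control,
on a self-contained synthetic electromagnetic model.

## The problem

MRI of patients with conductive implants (screws, wires, fixation hardware)
faces two coupled hazards at ultrahigh field: the RF transmit field induces
currents on the implant whose scattered fields (i) pile charge up at the
implant tips — local E-field and SAR hotspots, hence RF heating — and
(ii) distort the transmit field B1+ near the implant, producing signal
voids and shading. With a multi-channel transmit array, the complex drive
weights (the *excitation vector* `u`) are free parameters: this package
computes drives that suppress the implant coupling while keeping the
transmit field strong and uniform.

For an n-channel array, fields superpose linearly while SAR is quadratic:

    B1+(u, r) = Σ_c u_c B1+_c(r),        SAR(u, r) = uᴴ Q(r) u,

with Hermitian PSD matrices `Q(r) = σ(r)/(2ρ(r)) Σ_axis E*(r) E(r)ᵀ` built
from per-channel E-fields. The regulated safety quantity is SAR10g,max —
the maximum after exact 10 g mass averaging — compressed to virtual
observation points (VOPs) for use inside optimization loops.

Three static shims are implemented:

* **CP** — circular polarization, `u_n = exp(−2πi·n/N)`: the birdcage-like
  reference mode.
* **OP** — orthogonal projection: `U_OP ∝ Û_CP − Û_wc⟨Û_wc, Û_CP⟩`, where
  `U_wc` is the principal eigenvector of the summed Q-matrices over the
  implant ROI (the drive that maximizes implant-site power deposition).
* **GA** — an elitist multi-objective genetic algorithm (NSGA-II class)
  over unit-power drives, minimizing `(−mean_ROI |B1+|/SAR10g,max,
  COV_ROI |B1+|)`; the output is a Pareto front, from which an operating
  point is picked (utopia-distance policy by default).

The surrounding stages — a current-filament + thin-wire method-of-moments
synthetic EM model of eight 8-channel array configurations (A–H) around a
muscle-mimicking phantom, per-channel calibration against measured B1+
maps, and a bioheat + PRF-shift thermometry forward model — make the whole
workflow runnable end to end on a desk, with an HDF5 container to swap in
fields from any full-wave solver.

## Worked example

```python
import ptxshim as px
res = px.run_pipeline(seed=1234, with_thermometry=False)
print(res.table[["mean_b1_uT_per_sqrtkW", "cov_percent",
                 "pct_mean_vs_ref", "pct_cov_reduction_vs_ref"]].round(2))
```

prints (default scene: configuration H, 70 mm implant parallel to B0 at
30 mm depth, 5 mm grid; ~1 minute on one CPU):

```
        mean_b1_uT_per_sqrtkW  cov_percent  pct_mean_vs_ref  pct_cov_reduction_vs_ref
method
CP                       8.52        57.49             0.00                      0.00
OP                       6.20        69.55           -27.24                    -20.98
GA                      12.36        22.67            45.09                     60.57
```

Reading: the GA drive delivers ~45 % more ROI-mean B1+ per unit forward
power than CP and cuts the B1+ coefficient of variation by ~61 %, while OP
sacrifices B1+ strength to null the worst-case implant mode. At matched
ROI-mean B1+, the GA drive deposits ~5.6x less 10 g SAR at the implant
tips than CP (ratio 0.18), and the bioheat forecast for the 175 W / 5 min
heating paradigm shows tip heating of 0.72 K (GA) versus 6.16 K (CP)
(see `examples/` — one short script per capability).

A thin CLI mirrors the library for shell use:
`ptxshim scene|fields|shim|thermo|sweep|report --help`.

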