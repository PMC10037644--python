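# Methods

This note documents the models behind `ptxshim`, the defaults and why they
were chosen, and what the synthetic electromagnetic stand-in does and does
not capture.

## Scene and conventions

Right-handed coordinates; z is both the phantom axis and B0; all lengths
are millimetres in configuration files and SI internally; voxel values are
sampled at voxel centers, 0-based indices ordered (x, y, z).

The default scene is a cylindrical phantom, L = 300 mm, D = 170 mm, with
muscle-mimicking electrical properties at 297.2 MHz (the 7.0 T proton
frequency): εr = 58.24, σ = 0.769 S/m. Mass density is not part of the
electrical recipe; ρ = 1000 kg/m³ is assumed (configurable) since the
sucrose/PVP gels are essentially water-density. The implant is a 70 mm
wire of radius 1 mm (conductivity recorded as metadata; the scattering
solver treats it as a perfect conductor, which is indistinguishable from
copper at these frequencies). Its default pose is parallel to z at 30 mm
depth below the phantom surface, placed on the +y axis: with the standard
spherical convention (θ polar from +z, φ azimuth from +x), φ = 0 is then
the *tangential* direction at the implant site, so the full θ-sweep from
parallel (θ = 0) to transverse (θ = 90°, φ = 0) stays inside the phantom.
The target ROI is a cylinder L = 110 mm, R = 20 mm coaxial with the
implant, clipped to the phantom.

The default grid spacing is 5 mm. This is a desk-scale choice: the whole
pipeline (fields → SAR → three shims → thermometry) completes in about a
minute at ~5.5×10⁴ phantom voxels, while every geometric and algebraic
contract is resolution-independent and finer grids are a config option.
Implant voxelization uses a capsule (cylinder + hemispherical caps) with a
capture radius of at least the voxel half-diagonal, so a 1 mm wire still
owns the voxels it passes through on a 5 mm grid.

## Synthetic electromagnetic model

The transmit elements are driven current filaments radiating in an
unbounded homogeneous lossy medium with the complex wavenumber
k² = ω²μ₀(ε₀εr − iσ/ω) (branch with Im k < 0, e^{−jkr} time convention
e^{+iωt}). Loops are rectangular filament loops conformal to the 105 mm
element cylinder with uniform current; "fractionated" dipoles and
birdcage rungs are straight z-directed filaments with triangular and
uniform current profiles respectively. Element E-fields use the
vector-potential term E = −iωA; B is the analytic curl of A per segment.
The eight array configurations follow the loop-width law
W_n = 210·(π/16)·α_n mm, α_n ∈ {1, 1.25, 1.5, 1.75}, with all elements
20 mm off the phantom surface.

Per-channel normalization ("per √W forward power") scales each channel so
the power it deposits in the phantom, ∑ σ|E|²/2 dV, equals 1 W. Radiation
into air is thereby neglected — the only normalization available without a
port model, and consistent across channels and configurations.

The implant is solved as a thin-wire electric-field integral equation:
pulse current basis, point matching on the wire axis, reduced kernel
√(ρ² + a²), and singularity extraction of the static 1/R part of the
vector-potential term (the midpoint current at 21 segments is then within
0.5 % of the 161-segment solution). Node charges follow from continuity,
q = (I_in − I_out)/(iω), with zero current beyond the tips — charge
therefore accumulates at the end nodes, which is precisely the tip-hotspot
mechanism. Scattered E combines the vector-potential term of the segment
currents with the Coulomb term of the node charges; scattered B comes from
the currents. Total fields are the superposition of incident and
scattered, exactly linear in the drive vector.

Deliberately *not* modelled: phantom-boundary reflections and standing
waves, the RF shield, tuning/matching networks and their −15 dB port
criterion, inter-element coupling/decoupling transformers, and meander
details of fractionated dipoles. What the model preserves — and what the
tests assert — is the structure the shimming method works on: linear
superposition, near-resonant implant coupling (70 mm ≈ λ/2 in muscle at
297 MHz), tip charge accumulation, B1+ asymmetry beside the wire, and the
orientation dependence of the coupling. Conclusions about absolute field
or SAR magnitudes in a specific coil require full-wave fields, which can
be imported through the HDF5 container in place of the synthetic model.

One consequence worth stating: at 5 mm resolution with 10 g averaging, the
whole-phantom SAR10g,max under the CP drive is superficial (near the
elements) rather than at the implant tip — the tip hotspot is strongly
localized and dilutes under 10 g mass averaging. The tip elevation is
still present (the tip-region SAR10g exceeds the implant-free baseline by
~20 % under CP) and the GA reliably suppresses it; superficial SAR10g
maxima outside the implantation site are a recognized behaviour of these
arrays, not an artefact of this model.

## SAR bookkeeping

Point Q-matrices: Q(r) = σ/(2ρ) Σ_axis E*(r)E(r)ᵀ, Hermitian PSD by
construction (symmetrized against rounding; PSD tests use an eigenvalue
tolerance of 10⁻¹²·trace). Matrices are stored only for phantom voxels.

10 g averaging grows a cube symmetrically around each voxel over phantom
voxels only (air carries no mass) until the accumulated mass reaches 10 g,
weighting the outermost shell fractionally so every region's mass is
*exactly* 10 g. This is a simplification of the IEC/IEEE 62704-1 region
construction (no surface-conformal shape adaptation); it is deterministic,
order-independent, and exact for constant fields. Implemented with 3-D
summed-area tables, so the cost is linear in voxel count.

VOP compression: cores are picked greedily in descending spectral-norm
order; matrix Q is covered by core V when V + εS̄ − Q is PSD with
S̄ = (max spectral norm)·I. Published VOPs are V + εS̄, so evaluation can
never underestimate any source matrix and overestimates by at most
ε·‖S̄‖·‖u‖². Default ε = 0.05 (119 VOPs from ~5.5×10⁴ matrices on the
default scene). ε = 0 returns the identity compression (every matrix its
own VOP, exact evaluation) rather than running the dominance test, which
would otherwise still drop exactly-dominated matrices.

## Shimming

All shims are computed at unit total forward power, Σ|u_c|² = 1. This is
load-bearing: |B1+| is linear and SAR quadratic in ‖u‖, so the objective
B1+/SAR10g,max is scale-dependent and a search without power normalization
is ill-posed. The real overall scale K is applied afterwards by
`scale_to_limit`, K = √(limit/SAR10g,max(û)); the default limit in the
config is 20 W/kg (local extremity limit, normal operating mode — the
guidelines are cited by name in this field but the number lives in
configuration, not code).

The worst-case vector U_wc is the principal eigenvector of A = Σ_ROI Q(r)
using point-level Q restricted to the implant ROI (averaged10g is a
config option); its global phase is fixed by making the first
non-negligible component real positive. OP projects a reference drive
onto the orthogonal complement of U_wc and renormalizes; the projection of
a drive parallel to U_wc is rejected as degenerate.

The GA parameterizes candidates by 2n−1 reals — n magnitudes in [0, 1]
and n−1 phases (channel 1 fixed at phase 0, removing the flat global-phase
direction) — normalized to unit power before evaluation. Objectives:
f₁ = −mean_ROI |B1+|/SAR10g,max (SAR via VOPs inside the loop),
f₂ = COV_ROI |B1+|; implant-interior voxels are excluded from the B1+
statistics. The optimizer is an in-package NSGA-II (non-dominated sorting,
crowding distance, binary tournament, SBX η = 15, polynomial mutation
η = 20), defaults population 80, 60 generations, seed 1234, with a
10⁻⁶ relative function tolerance on the front's ideal point (10-generation
stall window). The final front is re-evaluated with the exact (non-VOP)
10 g set and re-filtered for nondomination. Everything is bitwise
reproducible for a fixed seed. An optional hard SAR constraint hook is
not enabled by default; the two objectives above are the contract.

Selection from the front defaults to minimal Euclidean distance to the
utopia point after min–max normalization of both objectives; a
max-strength-subject-to-COV-threshold policy is provided. (Note that for
a two-member front the min–max normalization maps the members to (0,1) and
(1,0) — equidistant from utopia — so meaningful selection needs fronts of
three or more members; ties resolve to the first index.)

## Calibration

The measured-vs-simulated objective min_X ‖X∘Xe∘B1_sim − Xe∘B1_meas‖ is
separable across channels, so it is solved in closed form per channel,
X_c = ⟨B1s_c, B1e_c⟩/⟨B1s_c, B1s_c⟩ over valid pixels (the Xe_c factor
cancels in the minimizer and is retained in the residual report). Invalid
pixels (e.g. implant regions) are masked out and provably cannot influence
the fit. Since no experimental maps ship with the package, measured maps
are emulated as true maps × hidden per-channel coefficients + complex
Gaussian noise; the noise-free problem recovers the coefficients to
machine precision and the error grows linearly with the noise amplitude.

## Thermometry

Heating follows the bioheat equation with zero perfusion (gel phantom,
no convection): ∂T/∂t = (k_t/(ρc))∇²T + SAR/c, explicit finite
differences with automatic stable dt ≤ Δx²ρc/(6k_t), insulated
(zero-flux) boundaries at the phantom surface — the scheme conserves
deposited energy exactly, which the tests verify. Defaults k_t = 0.55
W/(m·K), c = 3500 J/(kg·K) (PVP-gel-like; configurable). The heating
sequence is abstracted to its average deposited power: the paradigm's
input power (default 175 W for 300 s) scales the unit-power SAR map of
the chosen shim. Method comparisons are run at matched ROI-mean |B1+|
(equal imaging flip angle); matched total power is available as a switch.

PRF-shift readout: Δφ = 2πγ̄B₀α·ΔT·(TE₂−TE₁) + drift, with γ̄ = 42.577
MHz/T, α = −0.01 ppm/K (standard literature value), TE₁ = 2.26 ms,
TE₂ = 6.34 ms, B₀ = 7 T → −0.0764 rad/K. The drift is spatially uniform;
an oil region (α = 0) inside the FOV anchors the decode, which subtracts
the mean oil phase and inverts the encoding — exact for any drift.

## What passing tests do and do not show

The tests establish the algebraic contracts exactly (Q-matrix quadratic
forms, VOP certificates, 10 g mass bookkeeping, OP orthogonality,
worst-case maximality, GA front soundness, calibration recovery,
thermometry identities) and the qualitative physics on the synthetic
scene (tip charge accumulation, near-wire B1+ asymmetry, orientation
dependence with minimal coupling at θ = 90°, φ = 0°, GA improving both
B1+ uniformity and tip safety over CP). They do not certify absolute SAR
or temperature values for any real coil — those require full-wave fields
for the actual hardware, imported via the HDF5 container.

## Known limitations

* Homogeneous-medium kernels: no phantom-boundary reflections; absolute
  field magnitudes differ from full-wave results.
* The 10 g average is cube-grown, not surface-conformal.
* Static shims only; dynamic pTx / spokes pulse design is out of scope.
* One implant wire; no multi-implant interactions.
* The thermometry forward model ignores T1/T2*-weighting and noise of the
  actual dual-echo acquisition; phases are ideal.
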