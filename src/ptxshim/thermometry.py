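"""RF-heating forward model and PRF-shift thermometry encode/decode.

Heating follows the bioheat equation with zero perfusion (gel phantom):

    dT/dt = (k_t / (rho c)) laplacian(T) + SAR / c

integrated with an explicit finite-difference scheme on the scene grid,
insulated (zero-flux) boundaries at the phantom surface.  Temperature
change is read out the way an MR scanner would: the proton resonance
frequency shifts by alpha (~ -0.01 ppm/K), so the phase difference
between two gradient-echo images acquired at TE1 and TE2 encodes dT as

    dphi = 2 pi gamma_bar B0 alpha dT (TE2 - TE1) + drift

with a spatially uniform drift term; an oil reference (alpha = 0 in oil)
inside the field of view anchors the drift estimate on decode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GAMMA_BAR = 42.577e6  # Hz/T


class ThermoError(ValueError):
    pass


@dataclass
class ThermalProperties:
    """Phantom thermal constants (PVP-gel-like defaults), zero perfusion."""

    conductivity: float = 0.55   # W/(m K)
    heat_capacity: float = 3500  # J/(kg K)
    density: float = 1000.0      # kg/m^3
    perfusion: float = 0.0

    def __post_init__(self):
        if min(self.conductivity, self.heat_capacity, self.density) < 0:
            raise ThermoError("thermal properties must be non-negative")


@dataclass
class HeatingParadigm:
    input_power: float = 175.0   # W total forward power
    duration: float = 300.0      # s

    def __post_init__(self):
        if self.input_power < 0 or self.duration <= 0:
            raise ThermoError("power must be >= 0 and duration > 0")


@dataclass
class ThermometryProtocol:
    TE1: float = 2.26e-3         # s
    TE2: float = 6.34e-3         # s
    B0: float = 7.0              # T
    alpha_prf: float = -0.01e-6  # per K (ppm/K * 1e-6)
    drift: float = 0.0           # rad, global phase drift between acquisitions
    oil_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.TE2 <= self.TE1:
            raise ThermoError("TE2 must exceed TE1")

    @property
    def rad_per_kelvin(self) -> float:
        return 2 * np.pi * GAMMA_BAR * self.B0 * self.alpha_prf * (self.TE2 - self.TE1)


def stable_dt(spacing: float, props: ThermalProperties) -> float:
    """Explicit-scheme stability bound dt <= dx^2 rho c / (6 k_t)."""
    if props.conductivity == 0:
        return np.inf
    return spacing ** 2 * props.density * props.heat_capacity / (6 * props.conductivity)


def bioheat_forward(sar_map: np.ndarray, mask: np.ndarray, spacing: float,
                    props: ThermalProperties, paradigm: HeatingParadigm,
                    dt: float | None = None) -> np.ndarray:
    """Temperature rise (K) after the heating paradigm.

    ``sar_map`` is W/kg at unit (1 W) forward power on the full grid; it is
    scaled by the paradigm's input power.  Diffusion only couples voxels
    inside ``mask``; boundaries (phantom surface and grid edge) are
    insulated, which conserves the deposited energy.
    """
    limit = stable_dt(spacing, props)
    if dt is None:
        dt = min(limit / 2, paradigm.duration)
    elif dt > limit:
        raise ThermoError(f"dt={dt:g}s violates the stability bound {limit:g}s")
    sar = np.where(mask, sar_map, 0.0) * paradigm.input_power
    T = np.zeros_like(sar, dtype=float)
    alpha = props.conductivity / (props.density * props.heat_capacity)
    n_steps = max(1, int(np.ceil(paradigm.duration / dt)))
    dt = paradigm.duration / n_steps
    source = dt * sar / props.heat_capacity
    inv_h2 = 1.0 / spacing ** 2
    m = mask
    for _ in range(n_steps):
        if props.conductivity > 0:
            lap = np.zeros_like(T)
            for ax in range(3):
                fwd = np.roll(T, -1, axis=ax)
                bwd = np.roll(T, 1, axis=ax)
                m_fwd = np.roll(m, -1, axis=ax)
                m_bwd = np.roll(m, 1, axis=ax)
                # zero-flux: a face to a non-mask neighbor contributes nothing
                lap += np.where(m & m_fwd, fwd - T, 0.0)
                lap += np.where(m & m_bwd, bwd - T, 0.0)
            T = T + dt * alpha * inv_h2 * lap + source
        else:
            T = T + source
    return np.where(m, T, 0.0)


def prf_encode(dT: np.ndarray, proto: ThermometryProtocol,
               sample_mask: np.ndarray | None = None) -> np.ndarray:
    """Phase-difference map (rad) from a temperature-rise map.

    Oil voxels carry no PRF temperature sensitivity; every voxel (oil
    included) receives the uniform drift term.
    """
    phase = proto.rad_per_kelvin * np.asarray(dT, dtype=float)
    if proto.oil_mask is not None:
        phase = np.where(proto.oil_mask, 0.0, phase)
    phase = phase + proto.drift
    if sample_mask is not None:
        phase = np.where(sample_mask, phase, 0.0)
    return phase


def prf_decode(phase: np.ndarray, proto: ThermometryProtocol) -> np.ndarray:
    """Invert the PRF encoding with oil-referenced drift correction."""
    if proto.oil_mask is None or not np.any(proto.oil_mask):
        raise ThermoError("drift correction needs a non-empty oil mask")
    drift = float(np.mean(phase[proto.oil_mask]))
    dT = (phase - drift) / proto.rad_per_kelvin
    return np.where(proto.oil_mask, 0.0, dT)


def synthesize_oil_mask(phantom_mask: np.ndarray, n_voxels: int = 8) -> np.ndarray:
    """A small oil-reference region in the air corner of the grid.

    Stands in for the oil sample placed inside the field of view next to
    the phantom; it only needs to be outside the heated volume.
    """
    out = np.zeros_like(phantom_mask)
    free = np.flatnonzero(~phantom_mask.ravel())
    if len(free) == 0:
        raise ThermoError("no air voxels available for the oil reference")
    out.ravel()[free[:n_voxels]] = True
    return out
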