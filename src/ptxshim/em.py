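"""Synthetic per-channel electromagnetic model.

The transmit elements are modelled as driven current filaments radiating in
an unbounded homogeneous lossy medium (the phantom material), using the
complex-wavenumber free-space kernel e^{-jkR}/R.  The conductive implant is
a thin perfect-conductor wire: its induced current is solved with a
pulse-basis, point-matching method of moments (reduced kernel), and its
scattered fields are radiated back onto the grid from the solved segment
currents and the tip/line charges obtained from continuity.

This deliberately replaces a full-wave solve: phantom-boundary reflections,
the RF shield, matching networks and inter-element coupling are neglected.
What is preserved is the structure the shimming method manipulates — linear
superposition over channels, charge accumulation (SAR hotspots) at the wire
tips, B1+ asymmetry near the wire, and the orientation dependence of the
implant coupling.  Externally computed fields can be substituted through
the HDF5 container in :mod:`ptxshim.io`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import epsilon_0, mu_0
from scipy.interpolate import RegularGridInterpolator

from .scene import ArrayConfig, ImplantPose, Material, Scene, SceneError, VoxelGrid

DEFAULT_FREQUENCY = 297.2e6


class EMError(ValueError):
    pass


# ---------------------------------------------------------------------------
# filament geometry

@dataclass
class FilamentSet:
    """Straight current filaments driven by one channel.

    ``weights`` are relative complex current amplitudes per filament segment
    (uniform for loops and rungs, triangular taper for dipoles).
    """

    starts: np.ndarray   # (S, 3) m
    ends: np.ndarray     # (S, 3) m
    weights: np.ndarray  # (S,) complex

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.starts + self.ends)

    @property
    def dl(self) -> np.ndarray:
        return self.ends - self.starts

    @staticmethod
    def concat(parts: list["FilamentSet"]) -> "FilamentSet":
        return FilamentSet(
            np.concatenate([p.starts for p in parts]),
            np.concatenate([p.ends for p in parts]),
            np.concatenate([p.weights for p in parts]),
        )


def _polyline(points: np.ndarray, weight: complex, seg_len: float) -> FilamentSet:
    """Subdivide a polyline into filaments of roughly ``seg_len``."""
    starts, ends, w = [], [], []
    for p0, p1 in zip(points[:-1], points[1:]):
        n = max(1, int(np.ceil(np.linalg.norm(p1 - p0) / seg_len)))
        ts = np.linspace(0.0, 1.0, n + 1)[:, None]
        pts = p0 + ts * (p1 - p0)
        starts.append(pts[:-1])
        ends.append(pts[1:])
        w.append(np.full(n, weight, dtype=complex))
    return FilamentSet(np.vstack(starts), np.vstack(ends), np.concatenate(w))


def loop_filaments(azimuth: float, radius: float, length: float, width: float,
                   seg_len: float = 5e-3, n_arc: int = 8) -> FilamentSet:
    """Rectangular loop conformal to the element cylinder, uniform current."""
    half_ang = width / (2 * radius)
    angs = azimuth + np.linspace(-half_ang, half_ang, n_arc + 1)
    top = np.stack([radius * np.cos(angs), radius * np.sin(angs),
                    np.full_like(angs, length / 2)], axis=1)
    bottom = top.copy()
    bottom[:, 2] = -length / 2
    # closed rectangle traversed counter-clockwise seen from outside
    path = np.vstack([top, bottom[::-1], top[:1]])
    return _polyline(path, 1.0 + 0j, seg_len)


def dipole_filaments(azimuth: float, radius: float, length: float,
                     seg_len: float = 5e-3) -> FilamentSet:
    """z-directed dipole with triangular current taper (fractionated-dipole stand-in)."""
    n = max(4, int(np.ceil(length / seg_len)))
    zs = np.linspace(-length / 2, length / 2, n + 1)
    x = radius * np.cos(azimuth)
    y = radius * np.sin(azimuth)
    starts = np.stack([np.full(n, x), np.full(n, y), zs[:-1]], axis=1)
    ends = np.stack([np.full(n, x), np.full(n, y), zs[1:]], axis=1)
    zc = 0.5 * (zs[:-1] + zs[1:])
    taper = 1.0 - np.abs(zc) / (length / 2)
    return FilamentSet(starts, ends, taper.astype(complex))


def rung_filaments(azimuth: float, radius: float, length: float,
                   seg_len: float = 5e-3) -> FilamentSet:
    """Degenerate-birdcage rung: z-directed filament with uniform current."""
    n = max(2, int(np.ceil(length / seg_len)))
    zs = np.linspace(-length / 2, length / 2, n + 1)
    x = radius * np.cos(azimuth)
    y = radius * np.sin(azimuth)
    starts = np.stack([np.full(n, x), np.full(n, y), zs[:-1]], axis=1)
    ends = np.stack([np.full(n, x), np.full(n, y), zs[1:]], axis=1)
    return FilamentSet(starts, ends, np.ones(n, dtype=complex))


def build_array_filaments(cfg: ArrayConfig, seg_len: float = 5e-3) -> list[FilamentSet]:
    """One FilamentSet per transmit channel for array configurations A-H."""
    r = cfg.placement_radius
    azimuths = 2 * np.pi * np.arange(cfg.n_channels) / cfg.n_channels
    chans: list[FilamentSet] = []
    cid = cfg.config_id
    for i, az in enumerate(azimuths):
        parts: list[FilamentSet] = []
        if cid in "ABCD":
            parts.append(loop_filaments(az, r, cfg.loop_length, cfg.loop_width, seg_len))
        elif cid == "E":
            parts.append(dipole_filaments(az, r, cfg.dipole_length, seg_len))
        elif cid == "F":
            parts.append(rung_filaments(az, r, cfg.rung_length, seg_len))
        elif cid == "G":   # alternating rungs and dipoles
            if i % 2 == 0:
                parts.append(rung_filaments(az, r, cfg.rung_length, seg_len))
            else:
                parts.append(dipole_filaments(az, r, cfg.dipole_length, seg_len))
        elif cid == "H":   # loop-dipole module, co-driven
            parts.append(loop_filaments(az, r, cfg.loop_length, cfg.loop_width, seg_len))
            parts.append(dipole_filaments(az, r, cfg.dipole_length, seg_len))
        else:
            raise EMError(f"unknown array configuration {cid!r}")
        chans.append(FilamentSet.concat(parts))
    return chans


# ---------------------------------------------------------------------------
# medium and kernels

def complex_permittivity(material: Material, omega: float) -> complex:
    return epsilon_0 * material.eps_r - 1j * material.sigma / omega


def medium_wavenumber(material: Material, omega: float) -> complex:
    """k = omega * sqrt(mu0 * eps_c); branch with Im(k) <= 0 so e^{-jkR} decays."""
    k = np.sqrt(omega ** 2 * mu_0 * complex_permittivity(material, omega))
    if k.imag > 0:
        k = -k
    return complex(k)


def filament_fields(fil: FilamentSet, points: np.ndarray, k: complex, omega: float,
                    chunk: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """E and B of a filament set at ``points`` for unit drive current.

    E = -i*omega*A (vector-potential term only for the driven elements);
    B = curl A evaluated analytically per segment.  Returns (E, B) each
    (N, 3) complex, SI units per ampere of drive.
    """
    pts = np.asarray(points, dtype=float)
    E = np.zeros((len(pts), 3), dtype=complex)
    B = np.zeros((len(pts), 3), dtype=complex)
    centers, dl, w = fil.centers, fil.dl, fil.weights
    for i0 in range(0, len(centers), chunk):
        c = centers[i0:i0 + chunk]
        d = dl[i0:i0 + chunk] * w[i0:i0 + chunk, None]
        R = pts[:, None, :] - c[None, :, :]
        Rn = np.linalg.norm(R, axis=2)
        Rn = np.maximum(Rn, 1e-6)
        g = np.exp(-1j * k * Rn) / Rn
        # A-term
        E += (-1j * omega * mu_0 / (4 * np.pi)) * (g @ d)
        # curl term: (dl x Rhat) (1 + jkR) e^{-jkR} / R^2
        fac = (1 + 1j * k * Rn) * np.exp(-1j * k * Rn) / Rn ** 3
        cross = np.cross(np.broadcast_to(d, R.shape), R)
        B += (mu_0 / (4 * np.pi)) * np.einsum("ns,nsx->nx", fac, cross)
    return E, B


def b1_plus(B: np.ndarray) -> np.ndarray:
    """Rotating-frame transmit field B1+ = (Bx + i By) / 2 from an (..., 3) B array."""
    return 0.5 * (B[..., 0] + 1j * B[..., 1])


# ---------------------------------------------------------------------------
# field containers

@dataclass
class ChannelFieldSet:
    """Per-channel complex B1+ and E maps on a voxel grid, per sqrt(W) forward power.

    ``B1plus`` has shape (C, nx, ny, nz) in tesla; ``E`` has shape
    (C, 3, nx, ny, nz) in V/m. ``kind`` is incident / scattered / total.
    """

    grid: VoxelGrid
    B1plus: np.ndarray
    E: np.ndarray
    kind: str
    frequency: float = DEFAULT_FREQUENCY

    @property
    def n_channels(self) -> int:
        return self.B1plus.shape[0]

    def composite(self, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Superposed B1+ map and E map for a complex drive vector ``u``."""
        u = np.asarray(u, dtype=complex)
        if u.shape != (self.n_channels,):
            raise EMError("drive vector length does not match channel count")
        b1 = np.tensordot(u, self.B1plus, axes=(0, 0))
        e = np.tensordot(u, self.E, axes=(0, 0))
        return b1, e


@dataclass
class WireCurrents:
    """Thin-wire MoM solution: per-segment currents and per-node charges.

    ``currents`` is (n_segments, n_channels) in A per sqrt(W) channel drive;
    ``charges`` is (n_segments + 1, n_channels) in C per sqrt(W), obtained
    from continuity q_node = (I_in - I_out) / (i omega) with zero current
    beyond the wire tips.
    """

    pose: ImplantPose
    seg_centers: np.ndarray     # (S, 3) m
    node_points: np.ndarray     # (S+1, 3) m
    seg_length: float
    currents: np.ndarray        # (S, C) complex
    charges: np.ndarray         # (S+1, C) complex
    omega: float

    @property
    def tip_currents(self) -> np.ndarray:
        """Current at the two wire tips — identically zero by construction."""
        return np.zeros((2, self.currents.shape[1]))

    def total_norm(self) -> float:
        """Frobenius norm of the segment-current matrix (coupling strength)."""
        return float(np.linalg.norm(self.currents))


# ---------------------------------------------------------------------------
# incident fields

def element_incident_fields(filaments: list[FilamentSet], grid: VoxelGrid,
                            material: Material, phantom_mask: np.ndarray,
                            frequency: float = DEFAULT_FREQUENCY) -> ChannelFieldSet:
    """Incident per-channel fields on the grid, normalized per sqrt(W).

    Each channel is scaled so that the power it deposits in the phantom,
    P = sum sigma |E|^2 / 2 dV, equals 1 W — the package's "per sqrt(W)
    forward power" contract (radiation into air is neglected).
    """
    omega = 2 * np.pi * frequency
    k = medium_wavenumber(material, omega)
    pts = grid.points()
    _check_elements_outside(filaments, phantom_mask, grid)
    nC = len(filaments)
    shape = grid.shape
    B1 = np.empty((nC,) + shape, dtype=complex)
    E = np.empty((nC, 3) + shape, dtype=complex)
    sig = np.where(phantom_mask.ravel(), material.sigma, 0.0)
    dV = grid.voxel_volume
    for c, fil in enumerate(filaments):
        Ec, Bc = filament_fields(fil, pts, k, omega)
        p_dep = 0.5 * dV * float(np.sum(sig * np.sum(np.abs(Ec) ** 2, axis=1)))
        if p_dep <= 0:
            raise EMError("channel deposits no power in the phantom; cannot normalize")
        s = 1.0 / np.sqrt(p_dep)
        E[c] = (s * Ec).T.reshape((3,) + shape)
        B1[c] = b1_plus(s * Bc).reshape(shape)
    return ChannelFieldSet(grid=grid, B1plus=B1, E=E, kind="incident",
                           frequency=frequency)


def _check_elements_outside(filaments: list[FilamentSet], phantom_mask: np.ndarray,
                            grid: VoxelGrid) -> None:
    for fil in filaments:
        c = fil.centers
        idx = np.round((c - np.asarray(grid.origin)) / grid.spacing).astype(int)
        inside = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
        if inside.any():
            ii = idx[inside]
            if phantom_mask[ii[:, 0], ii[:, 1], ii[:, 2]].any():
                raise EMError("transmit element intersects the phantom volume")


# ---------------------------------------------------------------------------
# thin-wire method of moments

def _reduced_green(d: np.ndarray, a: float, k: complex) -> np.ndarray:
    R = np.sqrt(d ** 2 + a ** 2)
    return np.exp(-1j * k * R) / R


def _interp_E_at(fields: ChannelFieldSet, points: np.ndarray) -> np.ndarray:
    """Per-channel complex E interpolated at arbitrary points: (C, N, 3)."""
    g = fields.grid
    axes = tuple(g.axis_coords(i) for i in range(3))
    out = np.empty((fields.n_channels, len(points), 3), dtype=complex)
    for c in range(fields.n_channels):
        for ax in range(3):
            itp = RegularGridInterpolator(axes, fields.E[c, ax],
                                          bounds_error=False, fill_value=0.0)
            out[c, :, ax] = itp(points)
    return out


def solve_implant_currents(fields: ChannelFieldSet, implant: ImplantPose,
                           material: Material, n_segments: int = 21,
                           frequency: float | None = None) -> WireCurrents:
    """Induced current on the implant wire for every channel's incident field.

    Pulse-basis, point-matching electric-field integral equation on the wire
    axis with the reduced kernel sqrt(rho^2 + a^2); enforces zero total
    tangential E on the (perfectly conducting) wire.  Currents vanish
    identically beyond the tips, so charge piles up at the end nodes — the
    origin of the tip SAR hotspots.
    """
    if n_segments < 5:
        raise EMError("n_segments must be at least 5")
    if n_segments % 2 == 0:
        n_segments += 1          # odd count keeps a segment centered on the wire middle
    freq = frequency if frequency is not None else fields.frequency
    omega = 2 * np.pi * freq
    k = medium_wavenumber(material, omega)
    eps_c = complex_permittivity(material, omega)
    a = implant.radius
    L = implant.length
    delta = L / n_segments

    t_hat = implant.axis
    s_nodes = np.linspace(-L / 2, L / 2, n_segments + 1)
    s_centers = 0.5 * (s_nodes[:-1] + s_nodes[1:])
    c0 = np.asarray(implant.center)
    seg_centers = c0 + s_centers[:, None] * t_hat
    node_points = c0 + s_nodes[:, None] * t_hat

    # impedance matrix: vector-potential term + scalar-potential (charge) term.
    # The A-term integrates the kernel over the source segment with the static
    # 1/R part done analytically (singularity extraction), which keeps the
    # solve accurate at coarse segmentations.
    dcc = s_centers[:, None] - s_centers[None, :]
    dp = dcc + delta / 2
    dm = dcc - delta / 2
    static = np.log((dp + np.sqrt(dp ** 2 + a ** 2))
                    / (dm + np.sqrt(dm ** 2 + a ** 2)))
    Rmn = np.sqrt(dcc ** 2 + a ** 2)
    g_int = static + delta * (np.exp(-1j * k * Rmn) - 1.0) / Rmn
    Za = 1j * omega * mu_0 / (4 * np.pi) * g_int
    dnn = s_nodes[:, None] - s_nodes[None, :]
    Gnn = _reduced_green(dnn, a, k)
    # G(m+,n+) - G(m+,n-) - G(m-,n+) + G(m-,n-) for segments m, n
    Gpp = Gnn[1:, 1:]
    Gpm = Gnn[1:, :-1]
    Gmp = Gnn[:-1, 1:]
    Gmm = Gnn[:-1, :-1]
    Zq = (Gpp - Gpm - Gmp + Gmm) / (4 * np.pi * 1j * omega * eps_c * delta)
    Z = Za + Zq

    E_inc = _interp_E_at(fields, seg_centers)       # (C, S, 3)
    V = np.einsum("csx,x->sc", E_inc, t_hat)        # tangential drive per channel
    try:
        I = np.linalg.solve(Z, V)
    except np.linalg.LinAlgError as err:
        raise EMError(f"singular thin-wire impedance matrix: {err}") from None

    q = np.zeros((n_segments + 1, I.shape[1]), dtype=complex)
    I_pad = np.vstack([np.zeros((1, I.shape[1])), I, np.zeros((1, I.shape[1]))])
    q[:] = (I_pad[:-1] - I_pad[1:]) / (1j * omega)
    return WireCurrents(pose=implant, seg_centers=seg_centers,
                        node_points=node_points, seg_length=delta,
                        currents=I, charges=q, omega=omega)


def scattered_fields(currents: WireCurrents, grid: VoxelGrid, material: Material,
                     frequency: float = DEFAULT_FREQUENCY,
                     points: np.ndarray | None = None) -> ChannelFieldSet | tuple[np.ndarray, np.ndarray]:
    """Fields re-radiated by the implant currents and charges.

    E combines the vector-potential term of the segment currents with the
    Coulomb term of the node charges; B comes from the segment currents.
    If ``points`` is given, returns raw (E, B) arrays of shape (C, N, 3)
    instead of a grid ChannelFieldSet.
    """
    omega = currents.omega
    k = medium_wavenumber(material, omega)
    eps_c = complex_permittivity(material, omega)
    a = currents.pose.radius
    on_grid = points is None
    pts = grid.points() if on_grid else np.asarray(points, dtype=float)
    nC = currents.currents.shape[1]

    t_hat = currents.pose.axis
    # per-segment kernels, channel-independent; weight by per-channel currents after
    Rseg = pts[:, None, :] - currents.seg_centers[None, :, :]
    Rn = np.sqrt(np.sum(Rseg ** 2, axis=2) + a ** 2)
    g = np.exp(-1j * k * Rn) / Rn
    dl = currents.seg_length
    E = np.zeros((nC, len(pts), 3), dtype=complex)
    B = np.zeros((nC, len(pts), 3), dtype=complex)
    # E from A-term: -i omega mu0/(4 pi) * dl * t_hat * sum_n I_n g(r, n)
    EA = (-1j * omega * mu_0 / (4 * np.pi) * dl) * (g @ currents.currents)   # (N, C)
    E += EA.T[:, :, None] * t_hat[None, None, :]
    # B from currents: mu0/(4 pi) dl (t x Rhat)(1 + jkR) e^{-jkR}/R^2
    fac = (1 + 1j * k * Rn) * np.exp(-1j * k * Rn) / Rn ** 3                 # (N, S)
    cross = np.cross(np.broadcast_to(t_hat, Rseg.shape), Rseg)               # (N, S, 3)
    Bw = np.einsum("ns,sc,nsx->cnx", fac, currents.currents, cross)
    B += mu_0 / (4 * np.pi) * dl * Bw
    # E from charges: (1/4 pi eps_c) q (1 + jkR) e^{-jkR}/R^2 Rhat
    Rnode = pts[:, None, :] - currents.node_points[None, :, :]
    Rq = np.sqrt(np.sum(Rnode ** 2, axis=2) + a ** 2)
    facq = (1 + 1j * k * Rq) * np.exp(-1j * k * Rq) / Rq ** 3
    Eq = np.einsum("nj,jc,njx->cnx", facq, currents.charges, Rnode)
    E += Eq / (4 * np.pi * eps_c)

    if not on_grid:
        return E, B
    shape = grid.shape
    B1 = b1_plus(B).reshape((nC,) + shape)
    Eg = np.moveaxis(E, 2, 1).reshape((nC, 3) + shape)
    return ChannelFieldSet(grid=grid, B1plus=B1, E=Eg, kind="scattered",
                           frequency=frequency)


def assemble_total(incident: ChannelFieldSet, scattered: ChannelFieldSet) -> ChannelFieldSet:
    """Superpose incident and scattered channel fields."""
    if incident.grid != scattered.grid:
        raise EMError("incident and scattered fields are on different grids")
    if incident.n_channels != scattered.n_channels:
        raise EMError("channel count mismatch between incident and scattered fields")
    return ChannelFieldSet(grid=incident.grid,
                           B1plus=incident.B1plus + scattered.B1plus,
                           E=incident.E + scattered.E,
                           kind="total", frequency=incident.frequency)


def compute_fields(scene: Scene, n_segments: int = 21, seg_len: float = 5e-3,
                   frequency: float = DEFAULT_FREQUENCY) -> dict[str, ChannelFieldSet]:
    """Full field synthesis: incident, scattered (if an implant is placed), total."""
    fils = build_array_filaments(scene.array_config, seg_len=seg_len)
    inc = element_incident_fields(fils, scene.grid, scene.material,
                                  scene.phantom_mask, frequency)
    out = {"incident": inc}
    if scene.implant is not None:
        wc = solve_implant_currents(inc, scene.implant, scene.material,
                                    n_segments=n_segments)
        sca = scattered_fields(wc, scene.grid, scene.material, frequency)
        out["currents"] = wc
        out["scattered"] = sca
        out["total"] = assemble_total(inc, sca)
    else:
        out["total"] = inc
    return out
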