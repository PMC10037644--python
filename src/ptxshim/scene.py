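"""Voxelized phantom / implant / ROI geometry.

Everything downstream (field synthesis, SAR bookkeeping, shimming,
thermometry) consumes the :class:`Scene` built here: a muscle-mimicking
cylindrical phantom on a regular voxel grid, a thin conductive implant
placed inside it at a spherical-coordinate pose, and a cylindrical
target ROI coaxial with the implant.

Conventions
-----------
* Right-handed coordinates; the z axis is both the phantom axis and B0.
* All lengths in configuration dictionaries are millimetres; internal
  arrays and positions are SI (metres).
* Voxel values are sampled at voxel centers; indices are 0-based with
  axis order (x, y, z).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

MM = 1e-3

# Muscle-mimicking phantom at 297.2 MHz
DEFAULT_PHANTOM = dict(length_mm=300.0, diameter_mm=170.0,
                       eps_r=58.24, sigma=0.769, rho=1000.0)
# Copper-wire implant stand-in, 30 mm deep, parallel to B0
DEFAULT_IMPLANT = dict(length_mm=70.0, radius_mm=1.0, theta_deg=0.0,
                       phi_deg=0.0, depth_mm=30.0, sigma=5.8e8)
DEFAULT_ROI = dict(length_mm=110.0, radius_mm=20.0)
DEFAULT_GRID = dict(spacing_mm=5.0)


class SceneError(ValueError):
    """Invalid geometry or configuration."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular isotropic grid; ``origin`` is the center of voxel (0, 0, 0) in metres."""

    shape: tuple[int, int, int]
    spacing: float           # metres, isotropic
    origin: tuple[float, float, float]

    def __post_init__(self):
        if self.spacing <= 0:
            raise SceneError("grid spacing must be positive")

    @property
    def voxel_volume(self) -> float:
        return self.spacing ** 3

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing * np.arange(self.shape[axis])

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinate arrays broadcastable to ``shape`` (metres)."""
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z

    def points(self) -> np.ndarray:
        """All voxel centers as an (N, 3) array in grid raveling order."""
        x, y, z = self.coords()
        shp = self.shape
        return np.stack([np.broadcast_to(x, shp).ravel(),
                         np.broadcast_to(y, shp).ravel(),
                         np.broadcast_to(z, shp).ravel()], axis=1)


@dataclass(frozen=True)
class Material:
    """Homogeneous material constants: relative permittivity, conductivity (S/m), density (kg/m^3)."""

    eps_r: float
    sigma: float
    rho: float

    def __post_init__(self):
        if self.sigma < 0:
            raise SceneError("conductivity must be non-negative")


@dataclass(frozen=True)
class ImplantPose:
    """Pose of the thin cylindrical implant.

    theta is the polar angle from +z (degrees), phi the azimuth from +x;
    ``center`` is in metres. ``sigma`` is reported metadata — the wire is
    treated as a perfect conductor by the scattering solver.
    """

    center: tuple[float, float, float]
    theta: float
    phi: float
    length: float            # metres
    radius: float            # metres
    sigma: float = 5.8e8

    def __post_init__(self):
        if not (0.0 <= self.theta <= 180.0):
            raise SceneError("theta must lie in [0, 180] degrees")
        if not (0.0 <= self.phi < 360.0):
            raise SceneError("phi must lie in [0, 360) degrees")
        if self.length <= 0:
            raise SceneError("implant length must be positive")
        if self.radius >= self.length / 2:
            raise SceneError("implant radius must be smaller than half its length")

    @property
    def axis(self) -> np.ndarray:
        """Unit axis vector from the (theta, phi) spherical convention."""
        th = np.deg2rad(self.theta)
        ph = np.deg2rad(self.phi)
        return np.array([np.sin(th) * np.cos(ph),
                         np.sin(th) * np.sin(ph),
                         np.cos(th)])

    @property
    def tips(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center)
        h = self.axis * (self.length / 2)
        return c - h, c + h


@dataclass(frozen=True)
class ArrayConfig:
    """One of the eight transmit-array layouts A-H.

    Loop widths follow W_n = 210 mm * pi/16 * alpha_n; all elements sit on
    a cylinder 20 mm off the phantom surface (the shield at 30 mm is not
    part of the field model).
    """

    config_id: str
    n_channels: int = 8
    loop_length: float = 100 * MM
    loop_alpha: float | None = None     # None -> no loops in this design
    dipole_length: float | None = None  # None -> no dipoles
    rung_length: float | None = None    # degenerate-birdcage rungs
    placement_radius: float = (85 + 20) * MM
    shield_radius: float = (85 + 30) * MM

    @property
    def loop_width(self) -> float | None:
        if self.loop_alpha is None:
            return None
        return 210 * MM * np.pi / 16 * self.loop_alpha


_ARRAY_CONFIGS: dict[str, ArrayConfig] = {
    "A": ArrayConfig("A", loop_alpha=1.0),
    "B": ArrayConfig("B", loop_alpha=1.25),
    "C": ArrayConfig("C", loop_alpha=1.5),
    "D": ArrayConfig("D", loop_alpha=1.75),
    "E": ArrayConfig("E", loop_alpha=None, dipole_length=200 * MM),
    "F": ArrayConfig("F", loop_alpha=None, rung_length=100 * MM),
    "G": ArrayConfig("G", loop_alpha=None, rung_length=100 * MM,
                     dipole_length=200 * MM),
    "H": ArrayConfig("H", loop_alpha=1.0, dipole_length=200 * MM),
}


def array_config(config_id: str) -> ArrayConfig:
    try:
        return _ARRAY_CONFIGS[config_id.upper()]
    except KeyError:
        raise SceneError(f"unknown array configuration {config_id!r}; expected A-H")


@dataclass
class Scene:
    """Voxelized scene: grid, per-voxel material maps, masks, implant pose, array."""

    grid: VoxelGrid
    phantom_length: float
    phantom_radius: float
    material: Material
    eps_r: np.ndarray
    sigma: np.ndarray
    rho: np.ndarray
    phantom_mask: np.ndarray
    array_config: ArrayConfig
    implant: ImplantPose | None = None
    implant_mask: np.ndarray | None = None
    roi_mask: np.ndarray | None = None
    roi_length: float = 110 * MM
    roi_radius: float = 20 * MM

    @property
    def frequency(self) -> float:
        return 297.2e6

    def b1_valid_mask(self) -> np.ndarray:
        """Phantom voxels whose B1+ statistics are meaningful (implant interior excluded)."""
        m = self.phantom_mask.copy()
        if self.implant_mask is not None:
            m &= ~self.implant_mask
        return m


def _cylinder_mask(grid: VoxelGrid, radius: float, half_length: float) -> np.ndarray:
    x, y, z = grid.coords()
    return (x ** 2 + y ** 2 <= radius ** 2) & (np.abs(z) <= half_length)


def build_scene(config: Mapping | None = None) -> Scene:
    """Build the phantom scene from a (possibly partial) configuration mapping.

    Keys mirror the YAML schema: ``phantom{length_mm,diameter_mm,eps_r,sigma,rho}``,
    ``implant{length_mm,radius_mm,theta_deg,phi_deg,depth_mm[,center_mm],sigma}``,
    ``array{config_id}``, ``grid{spacing_mm}``.  The implant is placed unless
    ``implant`` is explicitly ``None`` in the config.
    """
    config = dict(config or {})
    ph = {**DEFAULT_PHANTOM, **(config.get("phantom") or {})}
    gr = {**DEFAULT_GRID, **(config.get("grid") or {})}
    roi = {**DEFAULT_ROI, **(config.get("roi") or {})}
    arr = config.get("array") or {}

    length = ph["length_mm"] * MM
    radius = ph["diameter_mm"] * MM / 2
    if length <= 0 or radius <= 0:
        raise SceneError("phantom dimensions must be positive")
    spacing = gr["spacing_mm"] * MM
    if spacing <= 0:
        raise SceneError("grid spacing must be positive")
    if 2 * radius / spacing < 8:
        raise SceneError("grid too coarse: fewer than 8 voxels across the phantom diameter")

    # grid = phantom bounding box + one-voxel margin, centered on the phantom
    def _axis(extent: float) -> tuple[int, float]:
        n = int(np.ceil(extent / spacing)) + 2
        return n, -(n - 1) / 2 * spacing

    nx, ox = _axis(2 * radius)
    nz, oz = _axis(length)
    grid = VoxelGrid(shape=(nx, nx, nz), spacing=spacing, origin=(ox, ox, oz))

    mat = Material(eps_r=ph["eps_r"], sigma=ph["sigma"], rho=ph["rho"])
    phantom_mask = _cylinder_mask(grid, radius, length / 2)
    eps = np.where(phantom_mask, mat.eps_r, 1.0)
    sig = np.where(phantom_mask, mat.sigma, 0.0)
    rho = np.where(phantom_mask, mat.rho, 0.0)

    scene = Scene(
        grid=grid, phantom_length=length, phantom_radius=radius,
        material=mat, eps_r=eps, sigma=sig, rho=rho,
        phantom_mask=phantom_mask,
        array_config=array_config(arr.get("config_id", "H")),
        roi_length=roi["length_mm"] * MM, roi_radius=roi["radius_mm"] * MM,
    )

    imp_cfg = config.get("implant", {})
    if imp_cfg is not None:
        imp = {**DEFAULT_IMPLANT, **imp_cfg}
        if "center_mm" in imp:
            center = tuple(np.asarray(imp["center_mm"], dtype=float) * MM)
        else:
            # 30 mm-deep pose on the +y axis: phi = 0 is then the tangential
            # direction, so transverse implant orientations stay inside the phantom
            center = (0.0, radius - imp["depth_mm"] * MM, 0.0)
        pose = ImplantPose(center=center, theta=imp["theta_deg"], phi=imp["phi_deg"],
                           length=imp["length_mm"] * MM, radius=imp["radius_mm"] * MM,
                           sigma=imp["sigma"])
        scene = place_implant(scene, pose)
        scene = implant_roi(scene)
    return scene


def _capsule_distance(points: np.ndarray, pose: ImplantPose) -> np.ndarray:
    """Distance from each point to the implant's axis segment."""
    a0, a1 = pose.tips
    axis = pose.axis
    rel = points - a0
    t = np.clip(rel @ axis, 0.0, pose.length)
    closest = a0 + t[:, None] * axis
    return np.linalg.norm(points - closest, axis=1)


def place_implant(scene: Scene, pose: ImplantPose) -> Scene:
    """Voxelize the implant as a capsule (cylinder + hemispherical caps).

    Raises :class:`SceneError` if the capsule protrudes outside the phantom.
    """
    # continuous protrusion check before voxelizing
    for tip in pose.tips:
        r_xy = np.hypot(tip[0], tip[1])
        if (r_xy + pose.radius > scene.phantom_radius
                or abs(tip[2]) + pose.radius > scene.phantom_length / 2):
            raise SceneError("implant protrudes outside the phantom")

    pts = scene.grid.points()
    dist = _capsule_distance(pts, pose)
    # a thin wire must still own the voxels it passes through: capture radius is
    # at least the voxel half-diagonal so the mask never comes out empty at
    # grids coarser than the wire radius
    capture = max(pose.radius, np.sqrt(3.0) / 2 * scene.grid.spacing)
    mask = (dist <= capture).reshape(scene.grid.shape)
    mask &= scene.phantom_mask
    out = replace_scene(scene, implant=pose, implant_mask=mask, roi_mask=None)
    return out


def implant_roi(scene: Scene) -> Scene:
    """Attach the cylindrical target ROI coaxial with the implant, clipped to the phantom."""
    if scene.implant is None or scene.implant_mask is None:
        raise SceneError("scene has no implant; place one before building the ROI")
    pose = scene.implant
    pts = scene.grid.points()
    rel = pts - np.asarray(pose.center)
    t = rel @ pose.axis
    radial = np.linalg.norm(rel - t[:, None] * pose.axis, axis=1)
    mask = ((np.abs(t) <= scene.roi_length / 2) & (radial <= scene.roi_radius))
    mask = mask.reshape(scene.grid.shape) & scene.phantom_mask
    mask |= scene.implant_mask
    return replace_scene(scene, roi_mask=mask)


def replace_scene(scene: Scene, **kw) -> Scene:
    """Shallow-copy a scene with some fields replaced."""
    return replace(scene, **kw)


def scene_config_hash(config: Mapping | None) -> str:
    """Stable short hash of a scene configuration for cache keys and provenance."""
    import hashlib
    import json

    blob = json.dumps(config or {}, sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
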