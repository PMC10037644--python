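"""ROI statistics, method-comparison tables, and implant-orientation sweeps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import em, sar, shim as shim_mod
from .nsga2 import GAConfig
from .scene import Scene, SceneError, build_scene

# Orientation grid in the spirit of the rotating-implant experiments: the
# implant stays at its 30 mm-deep pose and is rotated about its center, from
# parallel-to-B0 down to transverse, at the two azimuths that keep a 70 mm
# wire inside the phantom (phi = 0 is tangential for the default +y pose).
DEFAULT_SWEEP_ANGLES: tuple[tuple[float, float], ...] = (
    (0.0, 0.0), (30.0, 0.0), (45.0, 0.0), (60.0, 0.0), (90.0, 0.0),
    (30.0, 90.0), (45.0, 90.0),
)


class MetricsError(ValueError):
    pass


@dataclass
class ShimMetrics:
    """ROI statistics of one drive, presented the way coil papers tabulate them."""

    mean_b1: float             # uT / sqrt(kW) forward power
    std_b1: float              # uT / sqrt(kW), population std
    cov_percent: float         # 100 * std / mean
    sar10g_max: float | None = None   # W/kg at unit (1 W) forward power
    max_dT: float | None = None       # K, optional thermometry result

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def roi_statistics(b1_map: np.ndarray, roi_mask: np.ndarray,
                   forward_power: float = 1.0, ddof: int = 0) -> ShimMetrics:
    """Mean, std and COV of |B1+| over the ROI, normalized per sqrt(forward power).

    ``b1_map`` is a complex (or magnitude) full-grid map in tesla for a drive
    with total forward power ``forward_power`` watts.  Population standard
    deviation by default (``ddof=0``).
    """
    vals = np.abs(np.asarray(b1_map)[roi_mask])
    if vals.size == 0:
        raise MetricsError("ROI is empty")
    if forward_power <= 0:
        raise MetricsError("forward power must be positive")
    # tesla/sqrt(W) -> uT/sqrt(kW): 1e6 * sqrt(1000)
    scale = 1e6 * np.sqrt(1000.0) / np.sqrt(forward_power)
    mean = float(vals.mean() * scale)
    std = float(vals.std(ddof=ddof) * scale)
    cov = 100.0 * std / mean if mean > 0 else np.inf
    return ShimMetrics(mean_b1=mean, std_b1=std, cov_percent=cov)


def compare_methods(metrics: dict[str, ShimMetrics], reference: str = "CP"
                    ) -> pd.DataFrame:
    """Percent differences of means and COVs against the reference method:
    %(Mean_X/Mean_ref - 1) and %(1 - COV_X/COV_ref)."""
    if reference not in metrics:
        raise MetricsError(f"reference method {reference!r} missing")
    ref = metrics[reference]
    if ref.mean_b1 == 0:
        raise MetricsError("reference mean is zero")
    rows = []
    for name, m in metrics.items():
        rows.append({
            "method": name,
            "mean_b1_uT_per_sqrtkW": m.mean_b1,
            "cov_percent": m.cov_percent,
            "sar10g_max": m.sar10g_max,
            "max_dT": m.max_dT,
            "pct_mean_vs_ref": 100.0 * (m.mean_b1 / ref.mean_b1 - 1.0),
            "pct_cov_reduction_vs_ref": 100.0 * (1.0 - m.cov_percent / ref.cov_percent),
        })
    return pd.DataFrame(rows).set_index("method")


def tip_mask(scene: Scene, radius: float = 10e-3) -> np.ndarray:
    """Voxels within ``radius`` of either implant tip (hotspot assessment region)."""
    if scene.implant is None:
        raise MetricsError("scene has no implant")
    pts = scene.grid.points()
    t0, t1 = scene.implant.tips
    d = np.minimum(np.linalg.norm(pts - t0, axis=1),
                   np.linalg.norm(pts - t1, axis=1))
    return (d <= radius).reshape(scene.grid.shape) & scene.phantom_mask


def tip_sar10g_max(u: np.ndarray, q10: sar.QMatrixSet, mask: np.ndarray) -> float:
    """Maximum 10 g SAR of drive u restricted to the tip region."""
    flat = np.flatnonzero(mask.ravel())
    sel = np.isin(q10.voxel_index, flat)
    if not sel.any():
        raise MetricsError("tip region contains no stored Q voxels")
    sub = sar.QMatrixSet(grid=q10.grid, voxel_index=q10.voxel_index[sel],
                         Q=q10.Q[sel], level=q10.level)
    return sar.eval_sar(u, sub).max_value


# ---------------------------------------------------------------------------
# orientation sweep

def _sweep_config(base_config: dict | None, theta: float, phi: float) -> dict:
    """Sweep pose: rotate the implant about its (default 30 mm-deep) center."""
    cfg = dict(base_config or {})
    imp = dict(cfg.get("implant") or {})
    imp.update(theta_deg=theta, phi_deg=phi)
    cfg["implant"] = imp
    return cfg


def implant_current_sweep(base_config: dict | None = None,
                          angles=DEFAULT_SWEEP_ANGLES,
                          drive: np.ndarray | None = None,
                          n_segments: int = 21) -> pd.DataFrame:
    """Norm of the induced implant current under one drive, per orientation.

    The incident fields do not depend on the implant pose, so they are
    synthesized once; per orientation only the thin-wire solve is redone.
    Default drive is the CP mode.
    """
    if not len(angles):
        raise MetricsError("angle list is empty")
    scene0 = build_scene(_sweep_config(base_config, 0.0, 0.0))
    fils = em.build_array_filaments(scene0.array_config)
    inc = em.element_incident_fields(fils, scene0.grid, scene0.material,
                                     scene0.phantom_mask)
    u = drive if drive is not None else shim_mod.cp_vector(inc.n_channels).u
    rows = []
    for theta, phi in angles:
        sc = build_scene(_sweep_config(base_config, theta, phi))
        wc = em.solve_implant_currents(inc, sc.implant, sc.material,
                                       n_segments=n_segments)
        I_drive = wc.currents @ u
        rows.append({"theta": theta, "phi": phi,
                     "current_norm": float(np.linalg.norm(I_drive))})
    return pd.DataFrame(rows)


def orientation_sweep(base_config: dict | None = None,
                      angles=DEFAULT_SWEEP_ANGLES,
                      methods: tuple[str, ...] = ("CP", "OP", "GA"),
                      ga_config: GAConfig | None = None,
                      vop_epsilon: float = 0.05) -> pd.DataFrame:
    """Recompute shims and ROI metrics for each implant orientation.

    Rebuilds the scene (centered implant), regenerates the scattering, and
    recomputes every requested shim per pose; one row per (angle, method).
    Deterministic for a fixed GA seed.
    """
    if not len(angles):
        raise MetricsError("angle list is empty")
    scene0 = build_scene(_sweep_config(base_config, 0.0, 0.0))
    fils = em.build_array_filaments(scene0.array_config)
    inc = em.element_incident_fields(fils, scene0.grid, scene0.material,
                                     scene0.phantom_mask)
    rows = []
    for theta, phi in angles:
        sc = build_scene(_sweep_config(base_config, theta, phi))
        wcur = em.solve_implant_currents(inc, sc.implant, sc.material)
        sca = em.scattered_fields(wcur, sc.grid, sc.material)
        total = em.assemble_total(inc, sca)
        q = sar.point_q_matrices(total, sc.sigma, sc.rho, sc.phantom_mask)
        q10 = sar.average_q_10g(q, sc.rho, sc.grid)
        drives = compute_shims(total, sc, q, q10, methods, ga_config, vop_epsilon)
        valid = sc.b1_valid_mask() & sc.roi_mask
        for name, vec in drives.items():
            b1, _ = total.composite(vec.u)
            m = roi_statistics(b1, valid, forward_power=float(np.sum(np.abs(vec.u) ** 2)))
            m.sar10g_max = sar.eval_sar(vec.unit(), q10).max_value
            rows.append({"theta": theta, "phi": phi, "method": name,
                         **m.as_dict()})
    return pd.DataFrame(rows)


def compute_shims(total, scene: Scene, q_point: sar.QMatrixSet,
                  q10: sar.QMatrixSet, methods=("CP", "OP", "GA"),
                  ga_config: GAConfig | None = None,
                  vop_epsilon: float = 0.05) -> dict[str, shim_mod.ExcitationVector]:
    """CP / OP / GA drives for one scene (GA selected by the utopia policy)."""
    out: dict[str, shim_mod.ExcitationVector] = {}
    cp = shim_mod.cp_vector(total.n_channels)
    if "CP" in methods:
        out["CP"] = cp
    if "OP" in methods or "WC" in methods:
        uwc = shim_mod.worst_case_vector(q_point, scene.roi_mask)
        if "WC" in methods:
            out["WC"] = uwc
        if "OP" in methods:
            out["OP"] = shim_mod.op_vector(cp, uwc)
    if "GA" in methods:
        vops = sar.compress_vops(q10, epsilon=vop_epsilon)
        front = shim_mod.ga_shim(total, vops, scene.roi_mask,
                                 cfg=ga_config, exact_q10=q10,
                                 exclude_mask=scene.implant_mask)
        out["GA"] = shim_mod.select_solution(front)
        out["GA"].front = front     # stash for callers that need the full front
    return out
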