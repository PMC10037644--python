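"""Local SAR machinery: Q-matrices, 10 g averaging, VOP compression.

For an n-channel drive u (per sqrt(W)), the point SAR at voxel r is the
quadratic form u^H Q(r) u with Q(r) = sigma/(2 rho) * sum_axis E*(r) E(r)^T
assembled from the per-channel total E-fields.  Q-matrices are stored only
for phantom voxels (sparse voxel index).  The regulated quantity is the
maximum over 10 g mass-averaged regions; averaging uses symmetric cube
growth over phantom voxels with fractional weighting of the outermost
shell so every region's mass is exactly 10 g.  Virtual observation points
(VOPs) compress the averaged set to a few dominating matrices with a
certified overestimation factor for use inside optimization loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scene import Scene, VoxelGrid

TEN_GRAMS = 0.010  # kg


class SARError(ValueError):
    pass


@dataclass
class QMatrixSet:
    """Hermitian n x n SAR matrices at a sparse set of grid voxels."""

    grid: VoxelGrid
    voxel_index: np.ndarray       # (N,) flat indices into the grid
    Q: np.ndarray                 # (N, C, C) complex, W/kg per W
    level: str                    # "point" | "averaged10g"
    region_mass: np.ndarray | None = None   # (N,) kg, averaged10g only
    region_halfwidth: np.ndarray | None = None

    @property
    def n_channels(self) -> int:
        return self.Q.shape[1]

    def __len__(self) -> int:
        return len(self.voxel_index)


@dataclass
class VOPSet:
    """Dominating matrices: max_k u^H V_k u >= u^H Q u for every source Q."""

    vops: np.ndarray              # (K, C, C) complex, overestimation included
    epsilon: float                # fraction of the set's max spectral norm
    max_norm: float               # max spectral norm of the source set
    source_level: str = "averaged10g"
    provenance: str = ""

    @property
    def n_channels(self) -> int:
        return self.vops.shape[1]

    @property
    def overestimation_bound(self) -> float:
        """Worst-case absolute overestimation for a unit-power drive (W/kg)."""
        return self.epsilon * self.max_norm

    def __len__(self) -> int:
        return len(self.vops)


@dataclass
class SARResult:
    max_value: float
    argmax: int                   # flat voxel index (QMatrixSet) or VOP id
    values: np.ndarray | None = None


# ---------------------------------------------------------------------------

def point_q_matrices(fields, sigma: np.ndarray, rho: np.ndarray,
                     mask: np.ndarray | None = None) -> QMatrixSet:
    """Per-voxel point-SAR matrices from total per-channel E-fields.

    ``sigma`` and ``rho`` are full-grid maps; voxels with sigma == 0 get
    Q = 0 and are included only if inside ``mask`` (default: rho > 0).
    """
    if mask is None:
        mask = rho > 0
    if np.any((sigma > 0) & (rho <= 0) & mask):
        raise SARError("conductive voxel with non-positive density")
    flat = np.flatnonzero(mask.ravel())
    nC = fields.n_channels
    shape = fields.grid.shape
    Ev = fields.E.reshape(nC, 3, -1)[:, :, flat]          # (C, 3, N)
    w = (sigma.ravel()[flat] / (2.0 * np.maximum(rho.ravel()[flat], 1e-300)))
    Q = np.einsum("cxn,dxn->ncd", np.conj(Ev), Ev) * w[:, None, None]
    Q = 0.5 * (Q + np.conj(np.swapaxes(Q, 1, 2)))         # enforce exact Hermiticity
    return QMatrixSet(grid=fields.grid, voxel_index=flat, Q=Q, level="point")


# ---------------------------------------------------------------------------
# 10 g averaging via 3-D summed-area tables

def _prefix3(arr: np.ndarray) -> np.ndarray:
    p = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1, arr.shape[2] + 1) + arr.shape[3:],
                 dtype=arr.dtype)
    p[1:, 1:, 1:] = arr
    np.cumsum(p, axis=0, out=p)
    np.cumsum(p, axis=1, out=p)
    np.cumsum(p, axis=2, out=p)
    return p


def _cube_sum(prefix: np.ndarray, ii: np.ndarray, jj: np.ndarray, kk: np.ndarray,
              h: int, shape: tuple[int, int, int]) -> np.ndarray:
    lo = [np.clip(v - h, 0, n) for v, n in zip((ii, jj, kk), shape)]
    hi = [np.clip(v + h + 1, 0, n) for v, n in zip((ii, jj, kk), shape)]
    x0, y0, z0 = lo
    x1, y1, z1 = hi
    return (prefix[x1, y1, z1] - prefix[x0, y1, z1] - prefix[x1, y0, z1]
            - prefix[x1, y1, z0] + prefix[x0, y0, z1] + prefix[x0, y1, z0]
            + prefix[x1, y0, z0] - prefix[x0, y0, z0])


def average_q_10g(q: QMatrixSet, rho: np.ndarray, grid: VoxelGrid,
                  target_mass: float = TEN_GRAMS, max_halfwidth: int = 25) -> QMatrixSet:
    """Mass-averaged SAR matrices over grown cubes of exactly ``target_mass``.

    For each voxel a cube of phantom voxels is grown symmetrically until its
    mass reaches the target; the outermost shell enters with the fractional
    weight that makes the accumulated mass exact.  Air (rho == 0) carries no
    mass, so cubes near the phantom boundary grow farther into the phantom.
    """
    if q.level != "point":
        raise SARError("10 g averaging expects a point-level QMatrixSet")
    shape = grid.shape
    mass = (rho * grid.voxel_volume).astype(float)
    if mass.sum() < target_mass:
        raise SARError("phantom too small to accumulate the averaging mass anywhere")
    pm = _prefix3(mass)
    ii, jj, kk = np.unravel_index(q.voxel_index, shape)

    n = len(q)
    hsel = np.full(n, -1, dtype=int)
    m_in = np.zeros(n)
    m_out = np.zeros(n)
    pending = np.arange(n)
    prev_mass = np.zeros(n)      # cube mass at the previous halfwidth
    for h in range(0, max_halfwidth + 1):
        cm = _cube_sum(pm, ii[pending], jj[pending], kk[pending], h, shape)
        done = cm >= target_mass
        idx = pending[done]
        hsel[idx] = h
        m_in[idx] = prev_mass[idx]
        m_out[idx] = cm[done]
        prev_mass[pending] = cm
        pending = pending[~done]
        if len(pending) == 0:
            break
    if len(pending):
        raise SARError("averaging cube exceeded max halfwidth before reaching target mass")

    # mass-weighted Q sums, gathered at the required h per voxel
    nC = q.n_channels
    qgrid = np.zeros(shape + (nC * nC,), dtype=complex)
    qgrid.reshape(-1, nC * nC)[q.voxel_index] = q.Q.reshape(n, -1) * \
        mass.ravel()[q.voxel_index, None]
    pq = _prefix3(qgrid)

    Qavg = np.empty_like(q.Q)
    for h in np.unique(hsel):
        sel = np.flatnonzero(hsel == h)
        S_h = _cube_sum(pq, ii[sel], jj[sel], kk[sel], h, shape)
        if h > 0:
            S_in = _cube_sum(pq, ii[sel], jj[sel], kk[sel], h - 1, shape)
        else:
            S_in = np.zeros_like(S_h)
        m_inner = m_in[sel, None]
        m_outer = m_out[sel, None]
        w = (target_mass - m_inner) / (m_outer - m_inner)
        S = S_in + w * (S_h - S_in)
        Qavg[sel] = (S / target_mass).reshape(len(sel), nC, nC)
    Qavg = 0.5 * (Qavg + np.conj(np.swapaxes(Qavg, 1, 2)))
    return QMatrixSet(grid=grid, voxel_index=q.voxel_index, Q=Qavg,
                      level="averaged10g",
                      region_mass=np.full(n, target_mass),
                      region_halfwidth=hsel)


# ---------------------------------------------------------------------------
# VOP compression

def _spectral_norms(Q: np.ndarray) -> np.ndarray:
    return np.abs(np.linalg.eigvalsh(Q)).max(axis=1)


def compress_vops(q10: QMatrixSet, epsilon: float = 0.05,
                  provenance: str = "") -> VOPSet:
    """Compress an averaged Q-matrix set into dominating virtual observation points.

    A matrix Q is covered by core V when V + eps*Sbar - Q is positive
    semidefinite, Sbar = (max spectral norm of the set) * I.  Cores are
    picked greedily in descending spectral-norm order; the published VOPs
    are V + eps*Sbar so evaluation never underestimates and overestimates
    by at most eps * max-norm * ||u||^2.
    """
    if not (0.0 <= epsilon <= 0.5):
        raise SARError("epsilon must lie in [0, 0.5]")
    Q = q10.Q
    nC = q10.n_channels
    norms = _spectral_norms(Q)
    max_norm = float(norms.max())
    if epsilon == 0.0 or max_norm == 0.0:
        return VOPSet(vops=Q.copy(), epsilon=epsilon, max_norm=max_norm,
                      source_level=q10.level, provenance=provenance)
    slack = epsilon * max_norm * np.eye(nC)
    order = np.argsort(norms)[::-1]
    uncovered = order.copy()
    cores: list[np.ndarray] = []
    tol = -1e-12 * max_norm
    while len(uncovered):
        v = Q[uncovered[0]]
        cores.append(v)
        M = v[None] + slack[None] - Q[uncovered]
        min_eig = np.linalg.eigvalsh(M)[:, 0]
        uncovered = uncovered[min_eig < tol]
    vops = np.stack(cores) + slack[None]
    return VOPSet(vops=vops, epsilon=epsilon, max_norm=max_norm,
                  source_level=q10.level, provenance=provenance)


# ---------------------------------------------------------------------------
# evaluation

def _quadratic_forms(U: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Real quadratic forms u^H Q u for U (..., C) against Q (K, C, C) -> (..., K).

    Evaluated as (u* outer u) . Q_flat so the cost is one matmul; keeps no
    (B, K, C) intermediate.
    """
    single = np.ndim(U) == 1
    U = np.atleast_2d(U)
    B, C = U.shape
    M = (np.conj(U)[:, :, None] * U[:, None, :]).reshape(B, C * C)
    out = (M @ Q.reshape(len(Q), C * C).T).real
    return out[0] if single else out


def _max_quadratic_forms(U: np.ndarray, Q: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Max over Q of u^H Q u per row of U, chunked to bound memory."""
    U = np.asarray(U, dtype=complex)
    out = np.empty(len(U))
    for i in range(0, len(U), chunk):
        out[i:i + chunk] = _quadratic_forms(U[i:i + chunk], Q).max(axis=1)
    return out


def eval_sar(u: np.ndarray, matrices: QMatrixSet | VOPSet,
             full_map: bool = False) -> SARResult:
    """Maximum SAR of drive ``u`` over a Q-matrix or VOP set."""
    u = np.asarray(u, dtype=complex)
    Q = matrices.Q if isinstance(matrices, QMatrixSet) else matrices.vops
    if len(Q) == 0:
        raise SARError("empty SAR matrix set")
    if u.shape != (Q.shape[1],):
        raise SARError("drive vector length does not match the matrix set")
    vals = _quadratic_forms(u, Q)
    kmax = int(np.argmax(vals))
    arg = int(matrices.voxel_index[kmax]) if isinstance(matrices, QMatrixSet) else kmax
    return SARResult(max_value=float(vals[kmax]), argmax=arg,
                     values=vals if full_map else None)


def eval_sar_many(U: np.ndarray, matrices: QMatrixSet | VOPSet) -> np.ndarray:
    """Max-SAR values for a batch of drives, shape (B, C) -> (B,)."""
    Q = matrices.Q if isinstance(matrices, QMatrixSet) else matrices.vops
    return _max_quadratic_forms(np.asarray(U, dtype=complex), Q)


def sar_map(u: np.ndarray, matrices: QMatrixSet) -> np.ndarray:
    """Full-grid SAR map (W/kg) of drive ``u``; zero outside the stored voxels."""
    res = eval_sar(u, matrices, full_map=True)
    out = np.zeros(int(np.prod(matrices.grid.shape)))
    out[matrices.voxel_index] = res.values
    return out.reshape(matrices.grid.shape)
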