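"""Excitation-vector computation: CP, worst-case, orthogonal projection, GA.

Four kinds of static pTx shims are produced here:

* ``cp_vector`` — circular polarization, the birdcage-like reference mode
  with equal magnitudes and a -2*pi/n phase increment per channel.
* ``worst_case_vector`` — U_wc, the principal eigenvector of the summed
  Q-matrices over the implant ROI; the drive that maximizes RF power
  deposition at the implantation site.
* ``op_vector`` — orthogonal projection of a reference drive onto the
  complement of U_wc, nulling the worst-case implant coupling.
* ``ga_shim`` — multi-objective genetic-algorithm search over unit-power
  drives, trading off ROI-mean B1+ per unit worst-case 10 g SAR against
  B1+ uniformity (COV); returns the Pareto front.

All shims are computed at unit total forward power (sum |u_c|^2 = 1);
``scale_to_limit`` applies the real overall scale K that brings the
10 g SAR maximum to a prescribed safety limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nsga2 import GAConfig, GAResult, nondominated_mask, nsga2
from .sar import QMatrixSet, VOPSet, eval_sar, eval_sar_many


class ShimError(ValueError):
    pass


@dataclass
class ExcitationVector:
    """Complex per-channel drive weights with an overall real scale K."""

    u: np.ndarray
    K: float = 1.0
    normalization: str = "unit-power"     # "unit-power" | "scaled"
    method: str = ""
    seed: int | None = None

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=complex)

    @property
    def n_channels(self) -> int:
        return len(self.u)

    @property
    def scaled(self) -> np.ndarray:
        return self.K * self.u

    @property
    def total_power(self) -> float:
        return float(np.sum(np.abs(self.scaled) ** 2))

    def unit(self) -> np.ndarray:
        nrm = np.linalg.norm(self.u)
        if nrm == 0:
            raise ShimError("zero excitation vector")
        return self.u / nrm


@dataclass
class ShimObjectives:
    """Objective values of one drive: strength/safety and uniformity."""

    mean_B1_SARmax: float      # mean_roi |B1+| / SAR10g,max, uT/(W/kg) at unit power
    cov_B1_SARmax: float       # COV of |B1+| over the ROI (fraction)
    sar10g_max: float          # W/kg at unit power
    mean_B1: float             # mean_roi |B1+|, uT at unit power

    def as_array(self) -> np.ndarray:
        return np.array([-self.mean_B1_SARmax, self.cov_B1_SARmax])


@dataclass
class ParetoFront:
    members: list[tuple[ExcitationVector, ShimObjectives]]
    config: GAConfig
    convergence: list = field(default_factory=list)
    n_generations: int = 0

    def __len__(self) -> int:
        return len(self.members)

    def objective_matrix(self) -> np.ndarray:
        return np.stack([m[1].as_array() for m in self.members])


# ---------------------------------------------------------------------------

def cp_vector(n: int = 8, K: float = 1.0, unit_power: bool = True) -> ExcitationVector:
    """Circular-polarization mode: u_n = exp(-2*pi*i*n/N), 1 <= n <= N."""
    if n <= 0:
        raise ShimError("channel count must be positive")
    phases = -2 * np.pi * np.arange(1, n + 1) / n
    u = np.exp(1j * phases)
    if unit_power:
        u = u / np.sqrt(n)
    return ExcitationVector(u=u, K=K, method="CP")


def _fix_global_phase(u: np.ndarray) -> np.ndarray:
    """Make the first component with non-negligible magnitude real positive."""
    idx = np.flatnonzero(np.abs(u) > 1e-12 * np.abs(u).max())
    if len(idx) == 0:
        return u
    return u * np.exp(-1j * np.angle(u[idx[0]]))


def roi_correlation_matrix(q: QMatrixSet, roi_mask: np.ndarray) -> np.ndarray:
    """Summed Q-matrix (local RF power correlation matrix) over the ROI."""
    flat = np.flatnonzero(roi_mask.ravel())
    sel = np.isin(q.voxel_index, flat)
    if not sel.any():
        raise ShimError("ROI contains no stored Q-matrix voxels")
    return q.Q[sel].sum(axis=0)


def worst_case_vector(q: QMatrixSet, roi_mask: np.ndarray) -> ExcitationVector:
    """Principal eigenvector of the ROI power correlation matrix (U_wc)."""
    A = roi_correlation_matrix(q, roi_mask)
    vals, vecs = np.linalg.eigh(A)
    u = _fix_global_phase(vecs[:, -1])
    return ExcitationVector(u=u, method="WC")


def op_vector(u_ref: ExcitationVector, u_wc: ExcitationVector) -> ExcitationVector:
    """Orthogonal-projection shim: reference drive minus its U_wc component."""
    a = u_ref.unit()
    w = u_wc.unit()
    proj = a - w * np.vdot(w, a)
    nrm = np.linalg.norm(proj)
    if nrm < 1e-12:
        raise ShimError("reference drive is parallel to the worst-case vector; "
                        "projection is degenerate")
    return ExcitationVector(u=proj / nrm, method="OP")


# ---------------------------------------------------------------------------
# GA shimming

def _roi_b1_matrix(fields, roi_mask: np.ndarray, exclude: np.ndarray | None = None
                   ) -> np.ndarray:
    """(N_roi, C) complex B1+ per channel at valid ROI voxels (tesla per sqrt W)."""
    m = roi_mask.copy()
    if exclude is not None:
        m &= ~exclude
    flat = np.flatnonzero(m.ravel())
    if len(flat) == 0:
        raise ShimError("ROI is empty after exclusions")
    return fields.B1plus.reshape(fields.n_channels, -1)[:, flat].T


def _objectives(U: np.ndarray, B1roi: np.ndarray,
                matrices: QMatrixSet | VOPSet) -> np.ndarray:
    """(B, 2) = (-mean|B1|/SARmax, COV|B1|) for unit-power drives U (B, C), B1 in uT."""
    b = np.abs(U @ B1roi.T) * 1e6
    mean = b.mean(axis=1)
    cov = b.std(axis=1) / np.where(mean > 0, mean, np.inf)
    sar = eval_sar_many(U, matrices)
    f1 = -np.where(sar > 0, mean / sar, 0.0)
    return np.stack([f1, cov], axis=1)


def _decode(X: np.ndarray, n: int) -> np.ndarray:
    """Map 2n-1 box variables (n magnitudes, n-1 phases) to unit-power drives."""
    mags = X[:, :n]
    phases = np.concatenate([np.zeros((len(X), 1)), X[:, n:]], axis=1)
    u = mags * np.exp(1j * phases)
    nrm = np.linalg.norm(u, axis=1, keepdims=True)
    return u / np.where(nrm > 0, nrm, 1.0)


def ga_shim(fields, vops: VOPSet, roi_mask: np.ndarray,
            cfg: GAConfig | None = None,
            exact_q10: QMatrixSet | None = None,
            exclude_mask: np.ndarray | None = None) -> ParetoFront:
    """Multi-objective GA search for implant-friendly unit-power drives.

    Candidates are parameterized by 2n-1 reals (channel magnitudes plus
    phases with channel 1 fixed at phase 0) and power-normalized before
    evaluation.  Objective 1 is -mean_roi(|B1+|)/SAR10g,max with SAR from
    the VOP set; objective 2 is the COV of |B1+| over the ROI.  The final
    front is re-evaluated with the exact 10 g set when provided, and
    re-filtered for nondomination.
    """
    cfg = cfg or GAConfig()
    if vops.n_channels != fields.n_channels:
        raise ShimError("VOP set and field set disagree on channel count")
    n = fields.n_channels
    B1roi = _roi_b1_matrix(fields, roi_mask, exclude_mask)

    def f(X: np.ndarray) -> np.ndarray:
        U = _decode(X, n)
        dead = np.abs(U).sum(axis=1) == 0
        F = _objectives(U, B1roi, vops)
        F[dead] = [0.0, np.inf]
        return F

    lb = np.zeros(2 * n - 1)
    ub = np.concatenate([np.ones(n), np.full(n - 1, 2 * np.pi)])
    res: GAResult = nsga2(f, lb, ub, cfg)

    U = _decode(res.X, n)
    matrices = exact_q10 if exact_q10 is not None else vops
    F_exact = _objectives(U, B1roi, matrices)
    keep = nondominated_mask(F_exact)
    members = []
    for u, frow in zip(U[keep], F_exact[keep]):
        sar = float(eval_sar_many(u[None], matrices)[0])
        mean_b1 = float(np.abs(u @ B1roi.T).mean() * 1e6)
        obj = ShimObjectives(mean_B1_SARmax=float(-frow[0]), cov_B1_SARmax=float(frow[1]),
                             sar10g_max=sar, mean_B1=mean_b1)
        members.append((ExcitationVector(u=_fix_global_phase(u), method="GA",
                                         seed=cfg.seed), obj))
    # stable order: descending strength objective
    members.sort(key=lambda m: -m[1].mean_B1_SARmax)
    return ParetoFront(members=members, config=cfg, convergence=res.history,
                       n_generations=res.n_generations)


def select_solution(front: ParetoFront, policy: str = "utopia",
                    cov_threshold: float | None = None) -> ExcitationVector:
    """Pick one operating point from a Pareto front.

    ``utopia``: minimal Euclidean distance to the utopia point after
    min-max normalization of both objectives.  ``cov_threshold``: the
    member with maximal mean_B1_SARmax among those with COV <= threshold.
    """
    if len(front) == 0:
        raise ShimError("empty Pareto front")
    F = front.objective_matrix()
    if policy == "utopia":
        lo, hi = F.min(axis=0), F.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        Fn = (F - lo) / span
        idx = int(np.argmin(np.linalg.norm(Fn, axis=1)))
    elif policy == "cov_threshold":
        if cov_threshold is None:
            raise ShimError("cov_threshold policy requires a threshold")
        ok = np.flatnonzero(F[:, 1] <= cov_threshold)
        if len(ok) == 0:
            raise ShimError("no front member satisfies the COV threshold")
        idx = int(ok[np.argmin(F[ok, 0])])
    else:
        raise ShimError(f"unknown selection policy {policy!r}")
    return front.members[idx][0]


def scale_to_limit(u: ExcitationVector, q10: QMatrixSet | VOPSet,
                   sar_limit: float = 20.0) -> ExcitationVector:
    """Scale a unit-power drive so its 10 g SAR maximum equals ``sar_limit`` W/kg."""
    if sar_limit <= 0:
        raise ShimError("SAR limit must be positive")
    uhat = u.unit()
    sar = eval_sar(uhat, q10).max_value
    if sar <= 0:
        raise ShimError("drive deposits no SAR; cannot scale to a limit")
    K = float(np.sqrt(sar_limit / sar))
    return ExcitationVector(u=uhat, K=K, normalization="scaled",
                            method=u.method, seed=u.seed)
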