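"""Per-channel complex calibration between simulated and measured B1+ maps.

Real transmit chains introduce per-channel amplitude and phase errors
(cable losses, lumped-element tolerances, coupling to the surroundings)
that make measured per-channel B1+ maps differ from simulated ones by an
approximately constant complex factor per channel.  The calibration
estimates those factors by least squares over valid pixels and applies
them to simulation-derived excitation vectors before use on hardware.

The fitted objective min_X || X * Xe * B1_sim - Xe * B1_meas || is
separable across channels, so the minimizer is closed-form:
X_c = <B1_sim_c, B1_meas_c> / <B1_sim_c, B1_sim_c>  (the Xe_c factor
cancels; it is retained in the residual report).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .shim import ExcitationVector


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationProblem:
    """n x m simulated and measured per-channel B1+ maps with a validity mask."""

    B1_sim: np.ndarray         # (n, m) complex
    B1_meas: np.ndarray        # (n, m) complex
    Xe: np.ndarray             # (n,) complex drive used for the measurement
    valid_mask: np.ndarray | None = None   # (m,) bool

    def __post_init__(self):
        self.B1_sim = np.atleast_2d(np.asarray(self.B1_sim, dtype=complex))
        self.B1_meas = np.atleast_2d(np.asarray(self.B1_meas, dtype=complex))
        self.Xe = np.asarray(self.Xe, dtype=complex)
        if self.B1_sim.shape != self.B1_meas.shape:
            raise CalibrationError("simulated and measured maps differ in shape")
        n, m = self.B1_sim.shape
        if len(self.Xe) != n:
            raise CalibrationError("Xe length does not match channel count")
        if np.any(self.Xe == 0):
            raise CalibrationError("Xe must have no zero entries for calibrated channels")
        if self.valid_mask is None:
            self.valid_mask = np.ones(m, dtype=bool)
        if self.valid_mask.sum() < n:
            raise CalibrationError("fewer valid pixels than channels")


@dataclass
class CalibrationResult:
    X: np.ndarray              # (n,) complex coefficients
    residual: float            # norm of the masked weighted residual
    n_pixels: int


def calibrate_channels(p: CalibrationProblem) -> CalibrationResult:
    """Closed-form per-channel least squares over the valid pixels."""
    m = p.valid_mask
    S = p.B1_sim[:, m]
    M = p.B1_meas[:, m]
    denom = np.sum(np.abs(S) ** 2, axis=1)
    if np.any(denom == 0):
        raise CalibrationError("a channel's simulated map is zero on all valid pixels")
    X = np.sum(np.conj(S) * M, axis=1) / denom
    resid = np.linalg.norm(p.Xe[:, None] * (X[:, None] * S - M))
    return CalibrationResult(X=X, residual=float(resid), n_pixels=int(m.sum()))


def apply_calibration(X: np.ndarray, u: ExcitationVector) -> ExcitationVector:
    """Elementwise product X o u, renormalized to unit power."""
    X = np.asarray(X, dtype=complex)
    if len(X) != u.n_channels:
        raise CalibrationError("coefficient length does not match drive length")
    v = X * u.u
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise CalibrationError("calibration nulls the drive")
    return ExcitationVector(u=v / nrm, K=u.K, normalization=u.normalization,
                            method=u.method + "+cal", seed=u.seed)


def emulate_measured_maps(B1_sim: np.ndarray, X_true: np.ndarray,
                          noise_frac: float = 0.0,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """Synthetic 'measured' per-channel maps: true maps times hidden per-channel
    coefficients plus complex Gaussian noise at ``noise_frac`` of the RMS signal."""
    B1_sim = np.atleast_2d(np.asarray(B1_sim, dtype=complex))
    out = np.asarray(X_true, dtype=complex)[:, None] * B1_sim
    if noise_frac > 0:
        rng = rng or np.random.default_rng(0)
        scale = noise_frac * np.sqrt(np.mean(np.abs(out) ** 2))
        noise = rng.standard_normal(out.shape) + 1j * rng.standard_normal(out.shape)
        out = out + scale * noise / np.sqrt(2)
    return out
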