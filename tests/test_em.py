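"""Electromagnetic model: filament fields, thin-wire scattering, superposition."""

import numpy as np
import pytest
from scipy.constants import mu_0

from ptxshim import em
from ptxshim.scene import ImplantPose, Material, VoxelGrid


def _loop_polyline(radius, n_seg):
    ang = np.linspace(0, 2 * np.pi, n_seg + 1)
    return np.stack([radius * np.cos(ang), radius * np.sin(ang),
                     np.zeros_like(ang)], axis=1)


def _uniform_fieldset(grid, e_vec, n_channels=1):
    """Synthetic incident field set: spatially uniform E, zero B."""
    shape = grid.shape
    E = np.zeros((n_channels, 3) + shape, dtype=complex)
    for ax in range(3):
        E[:, ax] = e_vec[ax]
    B1 = np.zeros((n_channels,) + shape, dtype=complex)
    return em.ChannelFieldSet(grid=grid, B1plus=B1, E=E, kind="incident")


def _small_grid(spacing=5e-3, n=21):
    o = -(n - 1) / 2 * spacing
    return VoxelGrid(shape=(n, n, n), spacing=spacing, origin=(o, o, o))


MUSCLE = Material(eps_r=58.24, sigma=0.769, rho=1000.0)
AIR = Material(eps_r=1.0, sigma=0.0, rho=0.0)


class TestFilamentFields:
    def test_circular_loop_center_matches_magnetostatics(self):
        """In a lossless eps_r=1 medium at low frequency, B at the center of a
        circular loop is mu0*I/(2R)."""
        R = 0.05
        fil = em.FilamentSet(starts=_loop_polyline(R, 256)[:-1],
                             ends=_loop_polyline(R, 256)[1:],
                             weights=np.ones(256, dtype=complex))
        omega = 2 * np.pi * 1e3
        k = em.medium_wavenumber(AIR, omega)
        _, B = em.filament_fields(fil, np.array([[0.0, 0.0, 0.0]]), k, omega)
        assert abs(B[0, 2]) == pytest.approx(mu_0 / (2 * R), rel=1e-3)
        assert abs(B[0, 0]) < 1e-9 * abs(B[0, 2])

    def test_segment_refinement_converges(self):
        """Doubling the filament segment count moves |B1+| at the phantom
        center by less than 0.1 %."""
        omega = 2 * np.pi * em.DEFAULT_FREQUENCY
        k = em.medium_wavenumber(MUSCLE, omega)
        pt = np.array([[0.0, 0.0, 0.0]])
        vals = []
        for seg_len in (5e-3, 2.5e-3):
            fil = em.loop_filaments(0.0, 0.105, 0.1, 0.041, seg_len=seg_len)
            _, B = em.filament_fields(fil, pt, k, omega)
            vals.append(abs(em.b1_plus(B)[0]))
        assert abs(vals[1] - vals[0]) / vals[0] < 1e-3

    def test_e_scales_linearly_with_omega_at_fixed_kernel(self):
        """E = -i omega A: doubling omega at a fixed wavenumber doubles E."""
        fil = em.dipole_filaments(0.0, 0.105, 0.2)
        k = em.medium_wavenumber(MUSCLE, 2 * np.pi * em.DEFAULT_FREQUENCY)
        pt = np.array([[0.02, 0.0, 0.0]])
        omega = 2 * np.pi * em.DEFAULT_FREQUENCY
        E1, B1 = em.filament_fields(fil, pt, k, omega)
        E2, B2 = em.filament_fields(fil, pt, k, 2 * omega)
        np.testing.assert_allclose(E2, 2 * E1, rtol=1e-12)
        np.testing.assert_allclose(B2, B1, rtol=1e-12)

    def test_element_inside_phantom_rejected(self):
        grid = _small_grid()
        mask = np.ones(grid.shape, dtype=bool)
        fil = em.rung_filaments(0.0, 0.02, 0.05)   # well inside the mask
        with pytest.raises(em.EMError):
            em.element_incident_fields([fil], grid, MUSCLE, mask)


class TestWireCurrents:
    POSE = ImplantPose(center=(0, 0, 0), theta=0.0, phi=0.0,
                       length=0.07, radius=0.001)

    def test_perpendicular_drive_induces_no_current(self):
        grid = _small_grid()
        f_perp = _uniform_fieldset(grid, [100.0, 50.0, 0.0])
        f_par = _uniform_fieldset(grid, [0.0, 0.0, 100.0])
        I_perp = em.solve_implant_currents(f_perp, self.POSE, MUSCLE).currents
        I_par = em.solve_implant_currents(f_par, self.POSE, MUSCLE).currents
        assert np.linalg.norm(I_perp) < 1e-8 * np.linalg.norm(I_par)

    def test_uniform_parallel_drive_profile(self):
        """Symmetric current, maximal at the wire middle; tip charge dominates."""
        grid = _small_grid()
        wc = em.solve_implant_currents(_uniform_fieldset(grid, [0, 0, 100.0]),
                                       self.POSE, MUSCLE, n_segments=21)
        I = wc.currents[:, 0]
        np.testing.assert_allclose(np.abs(I), np.abs(I[::-1]), rtol=1e-9)
        assert np.argmax(np.abs(I)) == len(I) // 2
        assert np.all(wc.tip_currents == 0)
        # charge accumulates at the tips
        q = np.abs(wc.charges[:, 0])
        assert q[0] == pytest.approx(q.max())
        assert q[-1] == pytest.approx(q.max())

    def test_segment_refinement_midpoint_current(self):
        grid = _small_grid()
        f = _uniform_fieldset(grid, [0, 0, 100.0])
        I21 = em.solve_implant_currents(f, self.POSE, MUSCLE, n_segments=21).currents
        I41 = em.solve_implant_currents(f, self.POSE, MUSCLE, n_segments=41).currents
        mid21 = abs(I21[len(I21) // 2, 0])
        mid41 = abs(I41[len(I41) // 2, 0])
        assert abs(mid21 - mid41) / mid41 < 0.05

    def test_too_few_segments_rejected(self):
        grid = _small_grid()
        with pytest.raises(em.EMError):
            em.solve_implant_currents(_uniform_fieldset(grid, [0, 0, 1.0]),
                                      self.POSE, MUSCLE, n_segments=3)


class TestScatteredFields:
    POSE = TestWireCurrents.POSE

    def _solved(self):
        grid = _small_grid()
        wc = em.solve_implant_currents(_uniform_fieldset(grid, [0, 0, 100.0]),
                                       self.POSE, MUSCLE)
        return grid, wc

    def test_zero_currents_zero_fields(self):
        grid, wc = self._solved()
        wc.currents = np.zeros_like(wc.currents)
        wc.charges = np.zeros_like(wc.charges)
        sca = em.scattered_fields(wc, grid, MUSCLE)
        assert np.all(sca.E == 0) and np.all(sca.B1plus == 0)

    def test_linearity_in_currents(self):
        grid, wc = self._solved()
        sca1 = em.scattered_fields(wc, grid, MUSCLE)
        wc.currents = 2 * wc.currents
        wc.charges = 2 * wc.charges
        sca2 = em.scattered_fields(wc, grid, MUSCLE)
        np.testing.assert_allclose(sca2.E, 2 * sca1.E, rtol=1e-12)

    def test_scattered_e_peaks_at_wire_tips(self):
        """|E_sca| on a line 2 mm off-axis peaks within one segment of each tip."""
        grid, wc = self._solved()
        z = np.linspace(-0.05, 0.05, 201)
        line = np.stack([np.full_like(z, 2e-3), np.zeros_like(z), z], axis=1)
        E, _ = em.scattered_fields(wc, grid, MUSCLE, points=line)
        mag = np.linalg.norm(E[0], axis=1)
        half = len(z) // 2
        seg = wc.seg_length
        for zpk, tip in [(z[np.argmax(mag[:half])], -0.035),
                         (z[half + np.argmax(mag[half:])], 0.035)]:
            assert abs(zpk - tip) <= seg


class TestAssembleTotal:
    def test_zero_scattered_leaves_incident(self, coarse_bundle):
        inc = coarse_bundle["fields"]["incident"]
        zero = em.ChannelFieldSet(grid=inc.grid, B1plus=np.zeros_like(inc.B1plus),
                                  E=np.zeros_like(inc.E), kind="scattered")
        tot = em.assemble_total(inc, zero)
        np.testing.assert_array_equal(tot.B1plus, inc.B1plus)

    def test_superposition_is_exactly_linear(self, coarse_bundle, rng):
        total = coarse_bundle["total"]
        u = rng.standard_normal(8) + 1j * rng.standard_normal(8)
        b1, e = total.composite(u)
        b1_sum = sum(u[c] * total.B1plus[c] for c in range(8))
        np.testing.assert_allclose(b1, b1_sum, rtol=1e-12)
        alpha = 0.3 - 1.7j
        b1a, _ = total.composite(alpha * u)
        np.testing.assert_allclose(b1a, alpha * b1, rtol=1e-12)

    def test_grid_mismatch_rejected(self, coarse_bundle):
        inc = coarse_bundle["fields"]["incident"]
        other = em.ChannelFieldSet(grid=_small_grid(), B1plus=inc.B1plus,
                                   E=inc.E, kind="scattered")
        with pytest.raises(em.EMError):
            em.assemble_total(inc, other)


def test_channel_permutation_symmetry(coarse_bundle):
    """Rotating the scene and array by one element pitch permutes channels:
    the ROI-mean |B1+| of channel c should match channel c+1 after a 45 deg
    rotation of the evaluation points (8-fold array symmetry)."""
    total = coarse_bundle["total"]
    sc = coarse_bundle["scene"]
    # compare channel ROI statistics on the rotationally symmetric phantom
    mags = [np.abs(total.B1plus[c][sc.phantom_mask]).mean() for c in range(8)]
    assert np.std(mags) / np.mean(mags) < 0.05
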