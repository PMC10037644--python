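"""Shim computation: CP/worst-case/OP vectors, GA front, selection, scaling."""

import numpy as np
import pytest

from ptxshim import em, sar, shim
from ptxshim.nsga2 import GAConfig, nondominated_mask, nsga2
from ptxshim.scene import VoxelGrid

from conftest import random_unit_vectors


def _qset(Q):
    Q = np.asarray(Q, dtype=complex)
    return sar.QMatrixSet(grid=None, voxel_index=np.arange(len(Q)), Q=Q,
                          level="point")


class TestCPVector:
    def test_phase_increment_is_minus_45_degrees(self):
        u = shim.cp_vector(8).u
        inc = np.angle(u[1:] / u[:-1])
        np.testing.assert_allclose(inc, -np.pi / 4, rtol=1e-12)

    def test_equal_magnitudes_and_power(self):
        v = shim.cp_vector(8, K=2.0, unit_power=False)
        assert np.allclose(np.abs(v.u), 1.0)
        assert v.total_power == pytest.approx(8 * 2.0 ** 2)
        assert shim.cp_vector(8).total_power == pytest.approx(1.0)

    def test_invalid_channel_count(self):
        with pytest.raises(shim.ShimError):
            shim.cp_vector(0)


class TestWorstCase:
    def test_diagonal_matrix_returns_leading_basis_vector(self):
        A = np.diag([2.0, 1.0, 0.5, 0.1])
        # one voxel per diagonal entry so the ROI sum reproduces A
        qset = _qset([np.diag([2.0, 0, 0, 0]), np.diag([0, 1.0, 0, 0]),
                      np.diag([0, 0, 0.5, 0]), np.diag([0, 0, 0, 0.1])])
        qset.grid = VoxelGrid(shape=(4, 1, 1), spacing=1e-3, origin=(0, 0, 0))
        roi = np.ones((4, 1, 1), dtype=bool)
        u = shim.worst_case_vector(qset, roi).u
        np.testing.assert_allclose(np.abs(u), [1, 0, 0, 0], atol=1e-12)
        assert u[0].real > 0 and abs(u[0].imag) < 1e-12

    def test_rayleigh_maximality_against_random_sampling(self, rng):
        A = _random_hermitian_psd(8, rng)
        qset = _qset(A[None])
        qset.grid = VoxelGrid(shape=(1, 1, 1), spacing=1e-3, origin=(0, 0, 0))
        uwc = shim.worst_case_vector(qset, np.ones((1, 1, 1), bool)).u
        best = (np.conj(uwc) @ A @ uwc).real
        U = random_unit_vectors(100_000, 8, rng)
        samples = np.einsum("nc,cd,nd->n", np.conj(U), A, U).real
        assert np.all(samples <= best + 1e-12 * best)

    def test_identity_matrix_is_deterministic(self):
        qset = _qset(np.eye(4)[None])
        qset.grid = VoxelGrid(shape=(1, 1, 1), spacing=1e-3, origin=(0, 0, 0))
        roi = np.ones((1, 1, 1), bool)
        u1 = shim.worst_case_vector(qset, roi).u
        u2 = shim.worst_case_vector(qset, roi).u
        np.testing.assert_array_equal(u1, u2)
        assert np.linalg.norm(u1) == pytest.approx(1.0)
        nz = np.flatnonzero(np.abs(u1) > 1e-12)
        assert u1[nz[0]].real > 0


def _random_hermitian_psd(n, rng):
    A = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
    return A @ A.conj().T


class TestOPVector:
    def test_orthogonality_for_random_pairs(self, rng):
        for _ in range(1000):
            a = random_unit_vectors(1, 8, rng)[0]
            w = random_unit_vectors(1, 8, rng)[0]
            uop = shim.op_vector(shim.ExcitationVector(u=a),
                                 shim.ExcitationVector(u=w)).u
            assert abs(np.vdot(w, uop)) < 1e-12
            assert np.linalg.norm(uop) == pytest.approx(1.0)

    def test_orthogonal_reference_unchanged(self):
        a = shim.ExcitationVector(u=np.array([1, 0, 0, 0], complex))
        w = shim.ExcitationVector(u=np.array([0, 1, 0, 0], complex))
        np.testing.assert_allclose(shim.op_vector(a, w).u, a.u, atol=1e-15)

    def test_parallel_reference_rejected(self):
        a = shim.ExcitationVector(u=np.array([1, 1j, 0], complex))
        with pytest.raises(shim.ShimError):
            shim.op_vector(a, a)


class TestNSGA2:
    def test_schaffer_problem_front(self):
        """f1 = x^2, f2 = (x-2)^2: the Pareto set is x in [0, 2] with
        f2 = (sqrt(f1) - 2)^2."""
        def f(X):
            return np.stack([X[:, 0] ** 2, (X[:, 0] - 2) ** 2], axis=1)

        res = nsga2(f, [-5.0], [5.0], GAConfig(pop_size=40, generations=40, seed=3))
        assert np.all(nondominated_mask(res.F))
        assert np.all((res.X[:, 0] > -0.05) & (res.X[:, 0] < 2.05))
        expect_f2 = (np.sqrt(res.F[:, 0]) - 2) ** 2
        np.testing.assert_allclose(res.F[:, 1], expect_f2, atol=0.05)

    def test_seeded_determinism(self):
        def f(X):
            return np.stack([X[:, 0] ** 2 + X[:, 1] ** 2,
                             (X[:, 0] - 1) ** 2 + X[:, 1] ** 2], axis=1)
        cfg = GAConfig(pop_size=24, generations=15, seed=11)
        r1 = nsga2(f, [-2, -2], [2, 2], cfg)
        r2 = nsga2(f, [-2, -2], [2, 2], cfg)
        np.testing.assert_array_equal(r1.F, r2.F)


class TestGAShim:
    @pytest.fixture()
    def toy_problem(self, rng):
        """4-channel synthetic fieldset over a small ROI plus a 10g-like Q set."""
        shape = (6, 6, 6)
        grid = VoxelGrid(shape=shape, spacing=5e-3, origin=(0, 0, 0))
        E = rng.standard_normal((4, 3) + shape) * 10 + 1j * rng.standard_normal((4, 3) + shape) * 10
        B1 = (rng.standard_normal((4,) + shape) + 1j * rng.standard_normal((4,) + shape)) * 1e-7
        fields = em.ChannelFieldSet(grid=grid, B1plus=B1, E=E, kind="total")
        Q = np.stack([_random_hermitian_psd(4, rng) for _ in range(30)])
        q10 = sar.QMatrixSet(grid=grid, voxel_index=np.arange(30), Q=Q,
                             level="averaged10g")
        vops = sar.compress_vops(q10, epsilon=0.05)
        roi = np.zeros(shape, bool)
        roi.ravel()[:40] = True
        return fields, q10, vops, roi

    def test_front_is_nondominated_and_reproducible(self, toy_problem):
        fields, q10, vops, roi = toy_problem
        cfg = GAConfig(pop_size=24, generations=12, seed=5)
        f1 = shim.ga_shim(fields, vops, roi, cfg=cfg, exact_q10=q10)
        f2 = shim.ga_shim(fields, vops, roi, cfg=cfg, exact_q10=q10)
        assert len(f1) >= 1
        F = f1.objective_matrix()
        for i in range(len(F)):           # exhaustive pairwise dominance check
            for j in range(len(F)):
                if i != j:
                    assert not (np.all(F[j] <= F[i]) and np.any(F[j] < F[i]))
        np.testing.assert_array_equal(f1.objective_matrix(), f2.objective_matrix())

    def test_objectives_invariant_under_global_phase(self, toy_problem, rng):
        fields, q10, vops, roi = toy_problem
        from ptxshim.shim import _objectives, _roi_b1_matrix
        B1roi = _roi_b1_matrix(fields, roi)
        u = random_unit_vectors(1, 4, rng)
        F1 = _objectives(u, B1roi, vops)
        F2 = _objectives(u * np.exp(1j * 0.77), B1roi, vops)
        np.testing.assert_allclose(F1, F2, rtol=1e-12)

    def test_channel_mismatch_rejected(self, toy_problem):
        fields, q10, vops, roi = toy_problem
        bad = sar.VOPSet(vops=np.zeros((2, 6, 6), complex), epsilon=0.05, max_norm=1.0)
        with pytest.raises(shim.ShimError):
            shim.ga_shim(fields, bad, roi)


class TestSelectSolution:
    def _front(self, objs):
        members = [(shim.ExcitationVector(u=np.ones(2)),
                    shim.ShimObjectives(mean_B1_SARmax=-f1, cov_B1_SARmax=f2,
                                        sar10g_max=1.0, mean_B1=1.0))
                   for f1, f2 in objs]
        return shim.ParetoFront(members=members, config=GAConfig())

    def test_single_member(self):
        fr = self._front([(-10.0, 0.5)])
        assert shim.select_solution(fr) is fr.members[0][0]

    def test_two_member_utopia_enumeration(self):
        """Normalized objectives (-10,0.5)->(0,1), (-8,0.2)->(1,0): both are
        sqrt(1) from the utopia point... distances tie at 1, so check with an
        asymmetric third member where the answer is unambiguous."""
        fr = self._front([(-10.0, 0.5), (-8.0, 0.2), (-9.9, 0.25)])
        # normalized rows: (0, 1), (1, 0), (0.05, 1/6); member 3 is closest
        assert shim.select_solution(fr) is fr.members[2][0]

    def test_cov_threshold_policy(self):
        fr = self._front([(-10.0, 0.5), (-8.0, 0.2)])
        v = shim.select_solution(fr, policy="cov_threshold", cov_threshold=0.3)
        assert v is fr.members[1][0]
        with pytest.raises(shim.ShimError):
            shim.select_solution(fr, policy="cov_threshold", cov_threshold=0.1)

    def test_empty_front_rejected(self):
        with pytest.raises(shim.ShimError):
            shim.select_solution(shim.ParetoFront(members=[], config=GAConfig()))


class TestScaleToLimit:
    def test_closed_form_example(self):
        """SAR10g,max = 0.5 at unit power, limit 20 -> K = sqrt(40)."""
        qset = _qset([0.5 * np.eye(2)])
        u = shim.ExcitationVector(u=np.array([1.0, 0.0], complex))
        scaled = shim.scale_to_limit(u, qset, sar_limit=20.0)
        assert scaled.K == pytest.approx(np.sqrt(40.0), rel=1e-12)

    def test_scaled_vector_hits_limit(self, rng):
        Q = np.stack([_random_hermitian_psd(4, rng) for _ in range(10)])
        qset = _qset(Q)
        u = shim.ExcitationVector(u=random_unit_vectors(1, 4, rng)[0])
        scaled = shim.scale_to_limit(u, qset, sar_limit=20.0)
        sarval = sar.eval_sar(scaled.scaled, qset).max_value
        assert sarval == pytest.approx(20.0, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        qset = _qset([np.zeros((2, 2))])
        u = shim.ExcitationVector(u=np.array([1.0, 0.0], complex))
        with pytest.raises(shim.ShimError):
            shim.scale_to_limit(u, qset, sar_limit=0.0)
        with pytest.raises(shim.ShimError):
            shim.scale_to_limit(u, qset, sar_limit=20.0)
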