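import numpy as np
import pytest

import pchclust as pc
from pchclust.penalty import PenaltySpec, mcp_value, prox_pairs
from pchclust.prior import build_pair_index, to_partition
from pchclust.solver import (
    PCHState, _Workspace, initialize, objective_Q, update_centers,
    update_duals, update_fusion,
)

from conftest import fit_and_extract


def _random_state(data, pairs, rng, lam1=0.4, lam2=0.3, theta=0.9):
    q, p, A = data.q, data.p, pairs.n_pairs
    st = PCHState(
        beta=rng.normal(size=(q, data.n)), gamma=rng.normal(size=(p, data.n)),
        omega=rng.normal(size=(q, A)), eta=rng.normal(size=(p, A)),
        v=rng.normal(size=(q, A)), u=rng.normal(size=(p, A)),
        lambda1=lam1, lambda2=lam2, theta=theta, a=3.0,
    )
    for arr in (st.omega, st.eta, st.v, st.u):
        arr[:, pairs.is_prior] = 0.0
    return st


class TestObjective:
    def test_perfect_fit_identical_columns_is_zero(self):
        X = np.ones((2, 4))
        Z = np.full((3, 4), 2.0)
        data = pc.HierarchicalDataset(X=X, Z=Z)
        pairs = build_pair_index(4)
        st = PCHState(beta=X.copy(), gamma=Z.copy(),
                      omega=np.zeros((2, 6)), eta=np.zeros((3, 6)),
                      v=np.zeros((2, 6)), u=np.zeros((3, 6)),
                      lambda1=1.0, lambda2=1.0, theta=1.0, a=3.0)
        assert objective_Q(st, data, pairs) == 0.0

    def test_zero_centers_no_penalty(self, small_data):
        pairs = build_pair_index(small_data.n)
        st = PCHState(beta=np.zeros_like(small_data.X),
                      gamma=np.zeros_like(small_data.Z),
                      omega=np.zeros((3, 28)), eta=np.zeros((4, 28)),
                      v=np.zeros((3, 28)), u=np.zeros((4, 28)),
                      lambda1=0.0, lambda2=0.0, theta=1.0, a=3.0)
        expected = 0.5 * (np.sum(small_data.X**2) + np.sum(small_data.Z**2))
        assert objective_Q(st, small_data, pairs) == pytest.approx(expected)

    def test_matches_naive_double_loop(self, small_data, worked_prior):
        rng = np.random.default_rng(11)
        pairs = build_pair_index(small_data.n, worked_prior)
        st = _random_state(small_data, pairs, rng)
        got = objective_Q(st, small_data, pairs)
        # naive per-pair loop, straight from the penalized-objective definition
        spec1, spec2 = PenaltySpec(st.lambda1), PenaltySpec(st.lambda2)
        val = 0.5 * sum(
            np.sum((small_data.X[:, i] - st.beta[:, i]) ** 2)
            + np.sum((small_data.Z[:, i] - st.gamma[:, i]) ** 2)
            for i in range(small_data.n)
        )
        prior_set = worked_prior.pairs
        for j in range(small_data.n):
            for m in range(j + 1, small_data.n):
                if (j, m) in prior_set:
                    continue
                db = st.beta[:, j] - st.beta[:, m]
                dg = st.gamma[:, j] - st.gamma[:, m]
                val += mcp_value(np.sqrt(db @ db + dg @ dg), spec1)
                val += mcp_value(np.linalg.norm(db), spec2)
        assert got == pytest.approx(val)


class TestUpdateCenters:
    @pytest.mark.parametrize("use_prior", [False, True])
    def test_equals_direct_constrained_quadratic_solve(self, small_data,
                                                       worked_prior, use_prior):
        rng = np.random.default_rng(21)
        prior = worked_prior if use_prior else pc.PriorPairSet(n=8)
        part = to_partition(prior)
        pairs = build_pair_index(8, prior)
        ws = _Workspace(small_data, part, pairs, theta=0.7)
        st = _random_state(small_data, pairs, rng, theta=0.7)
        st = update_centers(st, ws)
        # oracle: solve the normal equations of the reduced block problem
        W = np.vstack([small_data.X, small_data.Z])
        P = np.vstack([0.7 * st.omega - st.v, 0.7 * st.eta - st.u])
        L, D = part.L, pairs.D.toarray()
        A = L.T @ L + 0.7 * L.T @ D.T @ D @ L
        T = np.linalg.solve(A.T, ((W + P @ D) @ L).T).T
        ref = T[:, part.labels]
        np.testing.assert_allclose(
            np.vstack([st.beta, st.gamma]), ref, atol=1e-8)

    def test_prior_blocks_share_columns(self, small_data, worked_prior):
        rng = np.random.default_rng(22)
        part = to_partition(worked_prior)
        pairs = build_pair_index(8, worked_prior)
        ws = _Workspace(small_data, part, pairs, theta=1.0)
        st = update_centers(_random_state(small_data, pairs, rng), ws)
        for block in [(0, 1, 3), (4, 5)]:
            for i in block[1:]:
                np.testing.assert_array_equal(st.beta[:, block[0]], st.beta[:, i])
                np.testing.assert_array_equal(st.gamma[:, block[0]], st.gamma[:, i])

    def test_theta_to_zero_limit_is_least_squares(self, small_data):
        part = to_partition(pc.PriorPairSet(n=8))
        pairs = build_pair_index(8)
        ws = _Workspace(small_data, part, pairs, theta=1e-12)
        rng = np.random.default_rng(23)
        st = _random_state(small_data, pairs, rng, theta=1e-12)
        st.v[:] = 0.0  # dual linear terms do not scale with theta
        st.u[:] = 0.0
        st = update_centers(st, ws)
        np.testing.assert_allclose(st.beta, small_data.X, atol=1e-8)
        np.testing.assert_allclose(st.gamma, small_data.Z, atol=1e-8)

    def test_no_prior_system_matches_In_plus_theta_DtD(self, small_data):
        # with an empty prior the K x K system is I_n + theta * D^T D
        theta = 1.3
        pairs = build_pair_index(8)
        D = pairs.D.toarray()
        M = np.eye(8) + theta * D.T @ D
        part = to_partition(pc.PriorPairSet(n=8))
        sizes = part.sizes.astype(float)
        c = 1.0 + theta * 8
        closed_inv = np.diag(1.0 / (c * sizes)) + theta / c
        np.testing.assert_allclose(closed_inv, np.linalg.inv(M), atol=1e-12)


class TestFusionAndDuals:
    def test_zero_lambdas_copy_input(self, small_data):
        rng = np.random.default_rng(31)
        pairs = build_pair_index(8)
        part = to_partition(pc.PriorPairSet(n=8))
        ws = _Workspace(small_data, part, pairs, 1.0)
        st = _random_state(small_data, pairs, rng, lam1=0.0, lam2=0.0, theta=1.0)
        st = update_fusion(st, ws)
        db = st.beta[:, pairs.j_idx] - st.beta[:, pairs.m_idx]
        dg = st.gamma[:, pairs.j_idx] - st.gamma[:, pairs.m_idx]
        np.testing.assert_allclose(st.omega, db + st.v, atol=1e-12)
        np.testing.assert_allclose(st.eta, dg + st.u, atol=1e-12)

    def test_identical_columns_zero_duals_give_zero_fusion(self):
        X = np.ones((2, 3))
        Z = np.ones((2, 3))
        data = pc.HierarchicalDataset(X=X, Z=Z)
        pairs = build_pair_index(3)
        part = to_partition(pc.PriorPairSet(n=3))
        ws = _Workspace(data, part, pairs, 1.0)
        st = PCHState(beta=X.copy(), gamma=Z.copy(),
                      omega=np.ones((2, 3)), eta=np.ones((2, 3)),
                      v=np.zeros((2, 3)), u=np.zeros((2, 3)),
                      lambda1=0.5, lambda2=0.5, theta=1.0, a=3.0)
        st = update_fusion(st, ws)
        np.testing.assert_array_equal(st.omega, 0)
        np.testing.assert_array_equal(st.eta, 0)

    def test_fusion_matches_per_pair_prox(self, small_data, worked_prior):
        rng = np.random.default_rng(32)
        pairs = build_pair_index(8, worked_prior)
        part = to_partition(worked_prior)
        ws = _Workspace(small_data, part, pairs, 0.9)
        st = _random_state(small_data, pairs, rng, theta=0.9)
        ref_os = st.beta[:, pairs.j_idx] - st.beta[:, pairs.m_idx] + st.v / 0.9
        ref_es = st.gamma[:, pairs.j_idx] - st.gamma[:, pairs.m_idx] + st.u / 0.9
        st = update_fusion(st, ws)
        om_ref, et_ref = prox_pairs(ref_os, ref_es, st.lambda1, st.lambda2, 3.0, 0.9)
        om_ref[:, pairs.is_prior] = 0.0
        et_ref[:, pairs.is_prior] = 0.0
        np.testing.assert_allclose(st.omega, om_ref, atol=1e-12)
        np.testing.assert_allclose(st.eta, et_ref, atol=1e-12)
        assert np.all(st.omega[:, pairs.is_prior] == 0.0)

    def test_dual_update_scalar_toy(self):
        # q = p = 1, n = 2, theta = 1: v_new = v + (beta1 - beta2 - omega)
        data = pc.HierarchicalDataset(X=[[0.0, 1.0]], Z=[[0.0, 2.0]])
        pairs = build_pair_index(2)
        part = to_partition(pc.PriorPairSet(n=2))
        ws = _Workspace(data, part, pairs, 1.0)
        st = PCHState(beta=np.array([[3.0, 1.0]]), gamma=np.array([[2.0, 2.0]]),
                      omega=np.array([[0.5]]), eta=np.array([[0.0]]),
                      v=np.array([[0.25]]), u=np.array([[0.0]]),
                      lambda1=0.1, lambda2=0.1, theta=1.0, a=3.0)
        st, resid = update_duals(st, ws)
        assert st.v[0, 0] == pytest.approx(0.25 + (3.0 - 1.0 - 0.5))
        assert st.u[0, 0] == pytest.approx(0.0)

    def test_zero_residual_leaves_duals_unchanged(self, small_data):
        rng = np.random.default_rng(33)
        pairs = build_pair_index(8)
        part = to_partition(pc.PriorPairSet(n=8))
        ws = _Workspace(small_data, part, pairs, 1.0)
        st = _random_state(small_data, pairs, rng)
        st.omega = st.beta[:, pairs.j_idx] - st.beta[:, pairs.m_idx]
        st.eta = st.gamma[:, pairs.j_idx] - st.gamma[:, pairs.m_idx]
        v0, u0 = st.v.copy(), st.u.copy()
        st, resid = update_duals(st, ws)
        assert resid == 0.0
        np.testing.assert_array_equal(st.v, v0)
        np.testing.assert_array_equal(st.u, u0)


class TestInitialize:
    def test_recovers_two_by_two_structure(self, separated_data):
        data, rough, refined = separated_data
        part = to_partition(pc.PriorPairSet(n=data.n))
        st = initialize(data, part, pc.SolverConfig(seed=0))
        assert np.unique(st.beta.round(3), axis=1).shape[1] == 2
        assert np.unique(st.gamma.round(3), axis=1).shape[1] == 4

    def test_empty_prior_matches_no_adjustment(self, separated_data):
        data, _, _ = separated_data
        part = to_partition(pc.PriorPairSet(n=data.n))
        st1 = initialize(data, part, pc.SolverConfig(seed=0))
        st2 = initialize(data, part, pc.SolverConfig(seed=0))
        np.testing.assert_array_equal(st1.beta, st2.beta)

    def test_all_samples_one_prior_block_forces_equal_columns(self, small_data):
        prior = pc.validate_and_close(
            [(i, i + 1) for i in range(7)], 8)
        part = to_partition(prior)
        st = initialize(small_data, part, pc.SolverConfig(seed=0))
        assert np.allclose(st.beta, st.beta[:, [0]])
        assert np.allclose(st.gamma, st.gamma[:, [0]])

    def test_single_sample_rejected(self):
        data = pc.HierarchicalDataset(X=[[1.0]], Z=[[1.0]])
        with pytest.raises(ValueError):
            initialize(data, to_partition(pc.PriorPairSet(n=1)),
                       pc.SolverConfig())


class TestFit:
    def test_large_lambdas_single_cluster(self, small_data):
        _, res = fit_and_extract(small_data, None, 50.0, 50.0, seed=0)
        assert res.K1 == res.K2 == 1

    def test_tiny_lambdas_all_singletons(self, small_data):
        state, res = fit_and_extract(small_data, None, 1e-8, 1e-8, seed=0)
        assert res.K1 == res.K2 == small_data.n
        np.testing.assert_allclose(state.beta, small_data.X, atol=1e-4)
        np.testing.assert_allclose(state.gamma, small_data.Z, atol=1e-4)

    def test_separated_structure_recovered_exactly(self, separated_data):
        data, rough, refined = separated_data
        state, res = fit_and_extract(data, None, 1.5, 1.0, seed=0)
        assert (res.K1, res.K2) == (2, 4)
        assert pc.ari(rough, res.rough_labels) == 1.0
        assert pc.ari(refined, res.refined_labels) == 1.0

    def test_prior_feasibility_exact_at_convergence(self, small_data, worked_prior):
        state, _ = fit_and_extract(small_data, worked_prior, 0.3, 0.2, seed=0)
        for block in [(0, 1, 3), (4, 5)]:
            for i in block[1:]:
                np.testing.assert_array_equal(
                    state.beta[:, block[0]], state.beta[:, i])
                np.testing.assert_array_equal(
                    state.gamma[:, block[0]], state.gamma[:, i])

    def test_primal_residual_below_tolerance(self, small_data):
        config = pc.SolverConfig(seed=0)
        state = pc.fit(small_data, None, 0.3, 0.2, config)
        pairs = build_pair_index(8)
        tol = config.tol_primal * np.sqrt(pairs.n_pairs * (3 + 4))
        assert state.converged
        assert state.residuals[-1] <= tol

    def test_center_update_never_increases_lagrangian(self, small_data):
        # the (beta, gamma) step is an exact block minimizer
        rng = np.random.default_rng(44)
        pairs = build_pair_index(8)
        part = to_partition(pc.PriorPairSet(n=8))
        ws = _Workspace(small_data, part, pairs, 1.0)

        def lagrangian(st):
            db = st.beta[:, pairs.j_idx] - st.beta[:, pairs.m_idx]
            dg = st.gamma[:, pairs.j_idx] - st.gamma[:, pairs.m_idx]
            return (0.5 * np.sum((small_data.X - st.beta) ** 2)
                    + 0.5 * np.sum((small_data.Z - st.gamma) ** 2)
                    + np.sum(st.v * (db - st.omega))
                    + np.sum(st.u * (dg - st.eta))
                    + 0.5 * np.sum((db - st.omega) ** 2)
                    + 0.5 * np.sum((dg - st.eta) ** 2))

        for trial in range(5):
            st = _random_state(small_data, pairs, rng, theta=1.0)
            before = lagrangian(st)
            st = update_centers(st, ws)
            assert lagrangian(st) <= before + 1e-9
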