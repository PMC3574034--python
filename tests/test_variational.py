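import numpy as np
import pytest

from mtgs._common import build_model_data
from mtgs.datamodel import (
    FixedEffectDesign,
    GenotypeMatrix,
    PhenotypeMatrix,
    PriorConfig,
)
from mtgs.variational import (
    ConvergenceSpec,
    converged,
    fit_varbayes,
    initialize_state,
    update_fixed_effects,
    update_pi,
    update_residual_cov,
    update_scale_matrix,
    update_snp_cov,
    update_snp_inclusion_and_effect,
    vb_impute_missing,
)


def _state_for(U, y, priors=None, design=None):
    geno = GenotypeMatrix(np.asarray(U, dtype=np.int8))
    pheno = PhenotypeMatrix(np.asarray(y, dtype=float))
    data = build_model_data(geno, pheno, design)
    state = initialize_state(data, priors or PriorConfig())
    return state, data


class TestConvergenceCriterion:
    def test_identical_vectors_converged(self):
        v = np.array([1.0, 2.0, 3.0])
        assert converged(v, v, ConvergenceSpec())

    @pytest.mark.parametrize(
        "delta,expected", [(1e-3, False), (1e-5, True)]
    )
    def test_relative_squared_change_threshold(self, delta, expected):
        curr = np.zeros(10)
        curr[0] = 1.0
        prev = curr.copy()
        prev[0] = 1.0 + delta
        # |diff|^2/|curr|^2 = delta^2 vs tolerance 1e-8
        assert converged(prev, curr, ConvergenceSpec(tolerance=1e-8)) is expected

    def test_zero_norm_only_converged_when_equal(self):
        z = np.zeros(3)
        assert converged(z, z, ConvergenceSpec())
        assert not converged(np.ones(3), z, ConvergenceSpec())

    def test_positive_tolerance_required(self):
        with pytest.raises(ValueError):
            ConvergenceSpec(tolerance=0.0)


class TestPiUpdate:
    @pytest.mark.parametrize(
        "N,sum_eg,expected",
        [(2, 1.0, 0.5), (100, 20.0, 81.0 / 102.0), (50, 50.0, 1.0 / 52.0)],
    )
    def test_beta_posterior_mean(self, N, sum_eg, expected):
        rng = np.random.default_rng(0)
        U = rng.integers(-1, 2, size=(6, N))
        state, _ = _state_for(U, rng.normal(size=(6, 2)),
                              PriorConfig(pi_mode="inferred"))
        state.e_gamma = np.full(N, sum_eg / N)
        update_pi(state)
        assert state.E_pi == pytest.approx(expected)
        assert state.beta_a == pytest.approx(N - sum_eg + 1)
        assert state.beta_b == pytest.approx(sum_eg + 1)


class TestSnpCovUpdate:
    def test_scalar_case(self):
        # T=1, E(gamma)=1, E(S)=s, ghat^2+V=v: E(sigma^{-2}) = (nu+1)/(s+v)
        state, _ = _state_for([[1], [0], [-1]], [[0.1], [0.2], [0.3]],
                              PriorConfig(nu=5.0))
        state.e_gamma[0] = 1.0
        state.g_hat[0] = [2.0]
        state.V_gl[0] = [[0.5]]
        state.ES = np.array([[1.5]])
        update_snp_cov(state, 0, nu=5.0)
        assert state.sigma_gl_inv[0, 0, 0] == pytest.approx(6.0 / (1.5 + 4.5))

    def test_excluded_snp_reverts_to_prior_expectation(self):
        # E(gamma)=0: E(Sigma_gl^{-1}) = nu * E(S)^{-1}
        rng = np.random.default_rng(1)
        state, _ = _state_for(rng.integers(-1, 2, size=(5, 2)),
                              rng.normal(size=(5, 2)))
        ES = np.array([[2.0, 0.3], [0.3, 1.0]])
        state.ES = ES
        state.e_gamma[1] = 0.0
        update_snp_cov(state, 1, nu=4.0)
        np.testing.assert_allclose(
            state.sigma_gl_inv[1], 4.0 * np.linalg.inv(ES)
        )

    def test_dense_solve_oracle_t2(self):
        rng = np.random.default_rng(2)
        state, _ = _state_for(rng.integers(-1, 2, size=(5, 2)),
                              rng.normal(size=(5, 2)))
        state.ES = np.array([[1.2, 0.4], [0.4, 0.8]])
        state.e_gamma[0] = 0.7
        state.g_hat[0] = [0.5, -0.3]
        state.V_gl[0] = np.array([[0.2, 0.05], [0.05, 0.3]])
        update_snp_cov(state, 0, nu=5.0)
        g = state.g_hat[0]
        expected = (5.0 + 0.7) * np.linalg.inv(
            state.ES + 0.7 * (np.outer(g, g) + state.V_gl[0])
        )
        np.testing.assert_allclose(state.sigma_gl_inv[0], expected)


class TestScaleMatrixUpdate:
    def test_scalar_case(self):
        # N=1, T=1, nu=5, E(sigma_g^{-2})=2: E(s) = (5+1+1)/2 = 3.5
        state, _ = _state_for([[1], [0], [-1]], [[0.1], [0.2], [0.3]])
        state.sigma_gl_inv = np.array([[[2.0]]])
        update_scale_matrix(state, nu=5.0)
        assert state.ES[0, 0] == pytest.approx(3.5)

    def test_homogeneous_case(self):
        # all E(Sigma_gl^{-1}) equal to M: E(S) = ((N nu + T + 1)/N) M^{-1}
        rng = np.random.default_rng(3)
        N = 4
        state, _ = _state_for(rng.integers(-1, 2, size=(6, N)),
                              rng.normal(size=(6, 2)))
        M = np.array([[3.0, 0.5], [0.5, 2.0]])
        state.sigma_gl_inv = np.tile(M, (N, 1, 1))
        update_scale_matrix(state, nu=5.0)
        np.testing.assert_allclose(
            state.ES, (N * 5.0 + 3) / N * np.linalg.inv(M)
        )

    def test_heterogeneous_dense_oracle(self):
        rng = np.random.default_rng(4)
        N = 3
        state, _ = _state_for(rng.integers(-1, 2, size=(6, N)),
                              rng.normal(size=(6, 2)))
        mats = []
        for _ in range(N):
            A = rng.normal(size=(2, 2))
            mats.append(A @ A.T + np.eye(2))
        state.sigma_gl_inv = np.array(mats)
        update_scale_matrix(state, nu=3.2)
        expected = (N * 3.2 + 3) * np.linalg.inv(np.sum(mats, axis=0))
        np.testing.assert_allclose(state.ES, expected)


class TestFixedEffectUpdate:
    def test_intercept_only_recovers_trait_means(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(20, 2)) + [1.5, -2.0]
        state, data = _state_for(rng.integers(-1, 2, size=(20, 3)), y)
        update_fixed_effects(state, data)
        np.testing.assert_allclose(state.Eb, y.mean(axis=0))

    def test_scale_equivariance(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=(15, 2))
        state, data = _state_for(rng.integers(-1, 2, size=(15, 2)), y)
        update_fixed_effects(state, data)
        Eb1, Vb1 = state.Eb.copy(), state.Vb.copy()
        state.E_sigma_e_inv = state.E_sigma_e_inv * 4.0
        update_fixed_effects(state, data)
        np.testing.assert_allclose(state.Eb, Eb1)
        np.testing.assert_allclose(state.Vb, Vb1 / 4.0)

    def test_gls_oracle_with_general_design(self):
        rng = np.random.default_rng(7)
        n, T, f = 12, 2, 3
        X = rng.normal(size=(n, T, f))
        y = rng.normal(size=(n, T))
        state, data = _state_for(
            rng.integers(-1, 2, size=(n, 2)), y, design=FixedEffectDesign(X)
        )
        re = state.E_sigma_e_inv
        update_fixed_effects(state, data)
        # independent dense GLS solve on the stacked system
        W = np.kron(np.eye(n), re)
        Xs = X.reshape(n * T, f)
        d = (y - data.U @ state.coef).reshape(n * T)
        expected = np.linalg.solve(Xs.T @ W @ Xs, Xs.T @ W @ d)
        np.testing.assert_allclose(state.Eb, expected, atol=1e-10)


class TestResidualCovUpdate:
    def test_single_trait_substitution(self):
        # T=1, n=10: E(sigma_e^{-2}) = (n-2)/RSS
        rng = np.random.default_rng(8)
        y = rng.normal(size=(10, 1))
        state, data = _state_for(rng.integers(-1, 2, size=(10, 2)), y)
        state.R = y.copy()
        update_residual_cov(state, data)
        rss = float((y ** 2).sum())
        assert state.E_sigma_e_inv[0, 0] == pytest.approx(8.0 / rss)

    def test_identity_scatter(self):
        # residual scatter = I at n = T+2 gives E(Sigma_e^{-1}) = I
        n, T = 4, 2
        state, data = _state_for(
            np.zeros((n, 1), dtype=int), np.zeros((n, T)) + np.arange(T)
        )
        R = np.zeros((n, T))
        R[0, 0] = R[1, 1] = 1.0   # R'R = I
        state.R = R
        update_residual_cov(state, data)
        np.testing.assert_allclose(state.E_sigma_e_inv, np.eye(T))

    def test_zero_residuals_reported_degenerate(self):
        state, data = _state_for(
            np.zeros((5, 1), dtype=int), np.zeros((5, 2))
        )
        state.R = np.zeros((5, 2))
        with pytest.raises(ValueError, match="degenerate|singular"):
            update_residual_cov(state, data)


class TestInclusionUpdate:
    def _prepared(self, pi_mode="fixed_value", pi_value=0.5):
        rng = np.random.default_rng(9)
        U = rng.integers(-1, 2, size=(25, 2))
        y = 0.8 * U[:, [0]] + rng.normal(size=(25, 2), scale=0.5)
        priors = PriorConfig(pi_mode=pi_mode, pi_value=pi_value, nu=5.0)
        return _state_for(U, y, priors)

    def test_pi_zero_forces_inclusion(self):
        state, data = self._prepared("fixed_zero", 0.0)
        update_snp_inclusion_and_effect(state, data, 0, pi=0.0)
        assert state.e_gamma[0] == 1.0

    def test_pi_one_forces_exclusion(self):
        state, data = self._prepared()
        update_snp_inclusion_and_effect(state, data, 0, pi=1.0)
        assert state.e_gamma[0] == 0.0
        np.testing.assert_array_equal(state.coef[0], 0.0)

    def test_orthogonal_residual_closed_form(self):
        # with ghat = 0 the odds reduce to (1-pi)c/((1-pi)c + pi) with
        # c = |V|^{1/2} |E(Sigma_l^{-1})|^{1/2}
        state, data = self._prepared()
        state.R[:] = 0.0
        state.coef[0] = 0.0
        pi = 0.5
        update_snp_inclusion_and_effect(state, data, 0, pi=pi)
        V = np.linalg.inv(
            state.sigma_gl_inv[0] * 0 + 5.0 * np.eye(2)
            + data.u_sq[0] * state.E_sigma_e_inv
        )
        c = np.sqrt(np.linalg.det(V) * np.linalg.det(5.0 * np.eye(2)))
        np.testing.assert_allclose(state.g_hat[0], 0.0, atol=1e-12)
        assert state.e_gamma[0] == pytest.approx(
            (1 - pi) * c / ((1 - pi) * c + pi)
        )

    def test_effect_identity_maintained(self):
        state, data = self._prepared()
        update_snp_inclusion_and_effect(state, data, 0, pi=0.5)
        np.testing.assert_allclose(
            state.coef[0], state.e_gamma[0] * state.g_hat[0]
        )
        np.testing.assert_allclose(
            state.e_gamma_ggt(0),
            state.e_gamma[0]
            * (np.outer(state.g_hat[0], state.g_hat[0]) + state.V_gl[0]),
        )


class TestImputation:
    def test_diagonal_covariance_imputes_zero(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=(8, 2))
        geno = GenotypeMatrix(rng.integers(-1, 2, size=(8, 2)).astype(np.int8))
        mask = np.ones((8, 2), dtype=bool)
        mask[:4, 1] = False
        pheno = PhenotypeMatrix(y, mask)
        data = build_model_data(geno, pheno)
        state = initialize_state(data, PriorConfig())
        state.Se = np.eye(2)
        update_fixed_effects(state, data)
        vb_impute_missing(state, data)
        np.testing.assert_allclose(state.R[:4, 1], 0.0, atol=1e-12)

    def test_bivariate_correlation_case(self):
        # T=2, unit variances, correlation rho, observed residual c -> rho*c
        rho, c = 0.6, 1.7
        y = np.array([[c, 0.0]] * 6)
        mask = np.ones((6, 2), dtype=bool)
        mask[:5, 1] = False
        geno = GenotypeMatrix(np.zeros((6, 1), dtype=np.int8))
        pheno = PhenotypeMatrix(y, mask)
        data = build_model_data(geno, pheno)
        state = initialize_state(data, PriorConfig())
        state.Se = np.array([[1.0, rho], [rho, 1.0]])
        state.Eb = np.zeros(2)
        state.R = y - 0.0
        state.coef[:] = 0.0
        vb_impute_missing(state, data)
        np.testing.assert_allclose(state.R[:5, 1], rho * c)

    def test_trivariate_matches_precision_route_oracle(self):
        # independent oracle: conditional mean via the precision matrix,
        # mu_m = -(P_mm)^{-1} P_mo e_o
        rng = np.random.default_rng(11)
        A = rng.normal(size=(3, 3))
        sigma = A @ A.T + 3 * np.eye(3)
        e_o = rng.normal(size=2)
        y = np.zeros((5, 3))
        y[:, :2] = e_o
        mask = np.ones((5, 3), dtype=bool)
        mask[:4, 2] = False
        geno = GenotypeMatrix(np.zeros((5, 1), dtype=np.int8))
        pheno = PhenotypeMatrix(y, mask)
        data = build_model_data(geno, pheno)
        state = initialize_state(data, PriorConfig())
        state.Se = sigma
        state.Eb = np.zeros(3)
        state.R = y.copy()
        state.coef[:] = 0.0
        vb_impute_missing(state, data)
        P = np.linalg.inv(sigma)
        expected = -np.linalg.solve(P[2:, 2:], P[2:, :2] @ e_o)
        np.testing.assert_allclose(state.R[:4, 2], expected[0], atol=1e-10)


class TestFitVarbayes:
    def test_deterministic(self, toy_data, shrinkage_priors):
        geno, pheno = toy_data
        a = fit_varbayes(geno, pheno, priors=shrinkage_priors)
        b = fit_varbayes(geno, pheno, priors=shrinkage_priors)
        np.testing.assert_array_equal(a.snp_effect_hat, b.snp_effect_hat)
        np.testing.assert_array_equal(a.sigma_e_hat, b.sigma_e_hat)

    def test_kernel_matches_reference_sweep(self, toy_data):
        geno, pheno = toy_data
        for mode in ("fixed_zero", "inferred"):
            priors = PriorConfig(pi_mode=mode)
            conv = ConvergenceSpec(max_iterations=30)
            fast = fit_varbayes(geno, pheno, priors=priors, conv=conv)
            ref = fit_varbayes(geno, pheno, priors=priors, conv=conv,
                               use_kernel=False)
            np.testing.assert_allclose(
                fast.snp_effect_hat, ref.snp_effect_hat, atol=1e-12
            )
            np.testing.assert_allclose(
                fast.inclusion_prob, ref.inclusion_prob, atol=1e-12
            )

    def test_fixed_point_self_consistency(self, toy_data, shrinkage_priors):
        from mtgs.variational import _vb_sweep_kernel

        geno, pheno = toy_data
        res = fit_varbayes(geno, pheno, priors=shrinkage_priors)
        assert res.diagnostics["status"] == "converged"
        # one extra full sweep moves the monitored vector less than tolerance
        data = build_model_data(geno, pheno)
        state = initialize_state(data, shrinkage_priors)
        conv = ConvergenceSpec()
        prev = state.monitored_vector()
        for _ in range(res.diagnostics["n_iterations"] + 1):
            _vb_sweep_kernel(state, data, shrinkage_priors, 5.0, True, True)
            curr = state.monitored_vector()
            if converged(prev, curr, conv):
                break
            prev = curr
        before = state.monitored_vector()
        _vb_sweep_kernel(state, data, shrinkage_priors, 5.0, True, True)
        assert converged(before, state.monitored_vector(), conv)

    def test_pi_zero_reduction_equals_pure_shrinkage(self, toy_data):
        geno, pheno = toy_data
        res = fit_varbayes(geno, pheno, priors=PriorConfig(pi_mode="fixed_zero"))
        assert (res.inclusion_prob == 1.0).all()
        assert res.pi_hat == 0.0

    def test_constant_phenotype_fixed_point(self):
        # constant y with intercept design: effects go to 0, Eb = the constant
        rng = np.random.default_rng(12)
        geno = GenotypeMatrix(rng.integers(-1, 2, size=(12, 4)).astype(np.int8))
        pheno = PhenotypeMatrix(np.full((12, 2), 3.5))
        res = fit_varbayes(geno, pheno, priors=PriorConfig(pi_mode="fixed_zero"),
                           fix_sigma_e=np.eye(2))
        np.testing.assert_allclose(res.snp_effect_hat, 0.0, atol=1e-6)
        np.testing.assert_allclose(res.b_hat, 3.5, atol=1e-6)

    def test_nonconvergence_reported_not_raised(self, toy_data, shrinkage_priors):
        geno, pheno = toy_data
        res = fit_varbayes(geno, pheno, priors=shrinkage_priors,
                           conv=ConvergenceSpec(tolerance=1e-30, max_iterations=5))
        assert res.diagnostics["status"] == "max_iterations"
        assert res.diagnostics["n_iterations"] == 5

    def test_single_trait_mode_merges_diagonal_structure(self, toy_data):
        geno, pheno = toy_data
        res = fit_varbayes(
            geno, pheno,
            priors=PriorConfig(pi_mode="fixed_zero", single_trait=True),
        )
        assert res.snp_effect_hat.shape == (geno.n_snps, 2)
        assert res.sigma_e_hat[0, 1] == 0.0   # no cross-trait coupling
        assert res.sigma_gl_hat[0][0, 1] == 0.0
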