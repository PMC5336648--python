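"""AECM engine: Woodbury algebra, E/CM steps, convergence, full fits.

Every low-rank computation is checked against a dense linear-algebra
oracle; the constrained noise updates are checked through the
expected-complete-data objective they are meant to maximize.
"""

import numpy as np
import pytest
from scipy import stats

from osgabi import (
    AitkenState,
    LoadingsSpec,
    ModelParams,
    aitken_converged,
    beta_matrix,
    cm_step_pi_mu,
    cm_step_psi,
    e_step_responsibilities,
    factor_moments,
    fit_grid,
    fit_single,
    logdet_identity,
    observed_loglik,
    woodbury_inverse,
)
from osgabi.aecm import DegenerateComponentError
from osgabi.core import contract_psi, covariance_from_params, expand_psi
from osgabi.simulate import SimulationDesign, generate_dataset
from osgabi.bicluster import adjusted_rand_index, map_classify
from conftest import random_binary_loadings, random_params


class TestWoodbury:
    def test_zero_loadings_collapse_to_diagonal_inverse(self):
        psi = np.array([0.5, 2.0, 4.0])
        lam = np.zeros((3, 1))
        np.testing.assert_allclose(woodbury_inverse(lam, psi), np.diag(1.0 / psi))
        assert logdet_identity(lam, psi) == pytest.approx(np.log(psi).sum())

    def test_two_by_two_analytic_inverse(self):
        lam = np.array([[1.0], [1.0]])
        psi = np.ones(2)
        # (Lambda Lambda' + I) = [[2,1],[1,2]], inverse [[2/3,-1/3],[-1/3,2/3]]
        np.testing.assert_allclose(
            woodbury_inverse(lam, psi),
            np.array([[2.0, -1.0], [-1.0, 2.0]]) / 3.0,
        )
        assert logdet_identity(lam, psi) == pytest.approx(np.log(3.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_instances_match_dense_oracles(self, seed):
        rng = np.random.default_rng(seed)
        lam = random_binary_loadings(8, 2, rng)
        psi = rng.uniform(0.1, 5.0, size=8)
        dense = lam @ lam.T + np.diag(psi)
        inv = woodbury_inverse(lam, psi)
        np.testing.assert_allclose(inv, np.linalg.inv(dense), atol=1e-8)
        np.testing.assert_allclose(inv @ dense, np.eye(8), atol=1e-8)
        assert logdet_identity(lam, psi) == pytest.approx(
            np.linalg.slogdet(dense)[1], abs=1e-8
        )

    def test_beta_analytic_and_dense(self, rng):
        lam = np.array([[1.0], [1.0]])
        np.testing.assert_allclose(beta_matrix(lam, np.ones(2)),
                                   [[1.0 / 3.0, 1.0 / 3.0]])
        lam8 = random_binary_loadings(8, 3, rng)
        psi8 = rng.uniform(0.2, 3.0, size=8)
        dense = lam8.T @ np.linalg.inv(lam8 @ lam8.T + np.diag(psi8))
        np.testing.assert_allclose(beta_matrix(lam8, psi8), dense, atol=1e-8)


class TestESteps:
    def test_single_component_gives_unit_responsibilities(self, rng):
        params = random_params("CUU", G=1, p=5, q=2, rng=rng)
        x = rng.normal(size=(7, 5))
        np.testing.assert_allclose(e_step_responsibilities(x, params), 1.0)

    def test_midpoint_of_symmetric_components_is_half_half(self, canonical_spec):
        mu = np.array([[-1.0] * 4, [1.0] * 4])
        params = ModelParams(
            model="CCC", G=2, pi=np.array([0.5, 0.5]), mu=mu,
            loadings=canonical_spec, psi=np.array(1.0),
        )
        z = e_step_responsibilities(np.zeros((1, 4)), params)
        np.testing.assert_allclose(z, [[0.5, 0.5]])

    @pytest.mark.parametrize("model", ["CUU", "UUC"])
    def test_matches_dense_multivariate_normal_oracle(self, model, rng):
        params = random_params(model, G=2, p=4, q=2, rng=rng)
        x = rng.normal(0, 2, size=(10, 4))
        dens = np.column_stack([
            params.pi[g] * stats.multivariate_normal.pdf(
                x, mean=params.mu[g], cov=covariance_from_params(params, g)
            )
            for g in range(2)
        ])
        oracle = dens / dens.sum(axis=1, keepdims=True)
        z = e_step_responsibilities(x, params)
        np.testing.assert_allclose(z, oracle, atol=1e-8)
        np.testing.assert_allclose(z.sum(axis=1), 1.0)
        assert observed_loglik(x, params) == pytest.approx(
            np.log(dens.sum(axis=1)).sum(), abs=1e-8
        )

    def test_extreme_outlier_never_produces_nan(self, canonical_spec):
        params = ModelParams(
            model="CCC", G=2, pi=np.array([0.5, 0.5]),
            mu=np.array([[0.0] * 4, [1.0] * 4]),
            loadings=canonical_spec, psi=np.array(0.01),
        )
        z = e_step_responsibilities(np.full((1, 4), 1e6), params)
        assert np.all(np.isfinite(z))
        np.testing.assert_allclose(z.sum(axis=1), 1.0)

    def test_duplicated_component_mixture_collapses(self, rng):
        one = random_params("CUU", G=1, p=5, q=2, rng=rng)
        two = ModelParams(
            model="CUU", G=2, pi=np.array([0.5, 0.5]),
            mu=np.vstack([one.mu, one.mu]), loadings=one.loadings,
            psi=np.vstack([one.psi, one.psi]),
        )
        x = rng.normal(size=(6, 5))
        assert observed_loglik(x, two) == pytest.approx(
            observed_loglik(x, one), abs=1e-8
        )


class TestCMSteps:
    def test_single_column_and_hard_assignments(self, rng):
        x = rng.normal(size=(6, 3))
        pi, mu = cm_step_pi_mu(x, np.ones((6, 1)))
        assert pi == pytest.approx([1.0])
        np.testing.assert_allclose(mu, x.mean(axis=0, keepdims=True))
        z = np.zeros((6, 2))
        z[:3, 0] = z[3:, 1] = 1.0
        pi, mu = cm_step_pi_mu(x, z)
        np.testing.assert_allclose(pi, [0.5, 0.5])
        np.testing.assert_allclose(mu[0], x[:3].mean(axis=0))
        np.testing.assert_allclose(mu[1], x[3:].mean(axis=0))

    def test_soft_weights_match_loop_oracle(self, rng):
        x = rng.normal(size=(6, 3))
        z = rng.dirichlet(np.ones(2), size=6)
        pi, mu = cm_step_pi_mu(x, z)
        for g in range(2):
            ng = sum(z[i, g] for i in range(6))
            assert pi[g] == pytest.approx(ng / 6)
            for j in range(3):
                expected = sum(z[i, g] * x[i, j] for i in range(6)) / ng
                assert mu[g, j] == pytest.approx(expected)
        assert pi.sum() == pytest.approx(1.0)

    def test_degenerate_component_raises(self, rng):
        x = rng.normal(size=(6, 3))
        z = np.zeros((6, 2))
        z[:, 0] = 1.0  # second component empty
        with pytest.raises(DegenerateComponentError):
            cm_step_pi_mu(x, z, n_g_floor=3)


class TestFactorMoments:
    def test_dominant_noise_limit(self, canonical_spec):
        # psi -> large: beta -> 0 and Theta -> I_q
        params = ModelParams(
            model="CCC", G=1, pi=np.array([1.0]), mu=np.zeros((1, 4)),
            loadings=canonical_spec, psi=np.array(1e8),
        )
        x = np.random.default_rng(0).normal(size=(12, 4))
        m = factor_moments(x, params, np.ones((12, 1)))
        np.testing.assert_allclose(m.beta[0], 0.0, atol=1e-6)
        np.testing.assert_allclose(m.Theta[0], np.eye(2), atol=1e-4)

    def test_scatter_and_theta_match_direct_formulas(self, rng):
        params = random_params("CUU", G=2, p=5, q=2, rng=rng)
        x = rng.normal(size=(20, 5))
        z = rng.dirichlet(np.ones(2), size=20)
        m = factor_moments(x, params, z)
        for g in range(2):
            lam = params.loadings.matrix_for(g)
            beta_dense = lam.T @ np.linalg.inv(covariance_from_params(params, g))
            np.testing.assert_allclose(m.beta[g], beta_dense, atol=1e-8)
            ng = z[:, g].sum()
            diff = x - params.mu[g]
            s = sum(z[i, g] * np.outer(diff[i], diff[i]) for i in range(20)) / ng
            np.testing.assert_allclose(m.S[g], s, atol=1e-10)
            np.testing.assert_allclose(
                m.Theta[g],
                np.eye(2) - m.beta[g] @ lam + m.beta[g] @ s @ m.beta[g].T,
                atol=1e-10,
            )
            assert np.allclose(m.S[g], m.S[g].T)
            assert np.all(np.linalg.eigvalsh(m.S[g]) >= -1e-10)


def q2_objective(params, moments):
    """Direct evaluation of the expected complete-data objective in Psi.

    Q2 = C + sum_g n_g/2 [ log|Psi_g^-1| - tr(Psi_g^-1 S_g)
         + 2 tr(Psi_g^-1 Lambda_g beta_g S_g) - tr(Psi_g^-1 Lambda_g Theta_g Lambda_g') ]
    """
    psi_gp = params.psi_matrix()
    total = 0.0
    for g in range(params.G):
        lam = params.loadings.matrix_for(g)
        pinv = np.diag(1.0 / psi_gp[g])
        b, s, th = moments.beta[g], moments.S[g], moments.Theta[g]
        total += moments.n_g[g] / 2.0 * (
            -np.log(psi_gp[g]).sum()
            - np.trace(pinv @ s)
            + 2.0 * np.trace(pinv @ lam @ b @ s)
            - np.trace(pinv @ lam @ th @ lam.T)
        )
    return total


class TestPsiUpdates:
    @pytest.mark.parametrize("model", ["CCC", "CCU", "CUC", "CUU",
                                       "UCC", "UCU", "UUC", "UUU"])
    def test_update_increases_q2(self, model, rng):
        """Each constrained update must not decrease the objective it maximizes."""
        params = random_params(model, G=2, p=6, q=2, rng=rng)
        x = rng.normal(0, 2, size=(40, 6))
        z = e_step_responsibilities(x, params)
        moments = factor_moments(x, params, z)
        before = q2_objective(params, moments)
        new_psi = cm_step_psi(params, moments)
        updated = ModelParams(
            model=model, G=2, pi=params.pi, mu=params.mu,
            loadings=params.loadings, psi=new_psi,
        )
        after = q2_objective(updated, moments)
        assert after >= before - 1e-8

    def test_constrained_updates_respect_structure(self, rng):
        params = random_params("UUU", G=2, p=6, q=2, rng=rng)
        x = rng.normal(size=(40, 6))
        z = e_step_responsibilities(x, params)
        moments = factor_moments(x, params, z)
        for model in ("CCC", "CUC", "CCU"):
            p2 = ModelParams(
                model=model, G=2, pi=params.pi, mu=params.mu,
                loadings=LoadingsSpec(matrices=[params.loadings.matrices[0]]),
                psi=contract_psi(params.psi_matrix(), model),
            )
            m2 = factor_moments(x, p2, z)
            out = expand_psi(cm_step_psi(p2, m2), model, 2, 6)
            if model[1] == "C":
                np.testing.assert_allclose(out[0], out[1])
            if model[2] == "C":
                assert np.ptp(out, axis=1) == pytest.approx(0.0)

    def test_fully_constrained_is_weighted_average_of_per_group_traces(self, rng):
        """psi(CCC) equals the n_g-weighted mean of the CUC per-group traces."""
        base = random_params("CUC", G=3, p=6, q=2, rng=rng)
        x = rng.normal(0, 2, size=(60, 6))
        z = e_step_responsibilities(x, base)
        moments = factor_moments(x, base, z)
        psi_cuc = cm_step_psi(base, moments)          # G-vector
        ccc = ModelParams(
            model="CCC", G=3, pi=base.pi, mu=base.mu, loadings=base.loadings,
            psi=contract_psi(base.psi_matrix(), "CCC"),
        )
        # same moments apply: CCC's psi was built from the same psi matrix?
        # no — recompute moments under the CCC parameters for a fair identity
        m_ccc = factor_moments(x, ccc, z)
        psi_ccc = cm_step_psi(ccc, m_ccc)
        w = m_ccc.n_g / m_ccc.n_g.sum()
        cuc_from_ccc_moments = cm_step_psi(
            ModelParams(model="CUC", G=3, pi=base.pi, mu=base.mu,
                        loadings=base.loadings,
                        psi=contract_psi(ccc.psi_matrix(), "CUC")),
            m_ccc,
        )
        assert float(psi_ccc) == pytest.approx(float(w @ cuc_from_ccc_moments))
        assert psi_cuc.shape == (3,)


class TestAitken:
    def test_flat_sequence_converges(self):
        assert aitken_converged(AitkenState(-100.0, -100.0, -100.0))

    def test_hand_computed_geometric_sequence(self):
        state = AitkenState(-110.0, -105.0, -102.5)
        assert state.a == pytest.approx(0.5)
        assert state.l_inf == pytest.approx(-100.0)
        # asymptotic gain 5 >= 0.1: not converged
        assert not aitken_converged(state, epsilon=0.1)

    def test_fast_geometric_decay_converges(self):
        # ratio 0.01, current step 1e-3: l_inf - l = 1e-3/(1-0.01) ~ 1e-3 < 0.1
        state = AitkenState(-100.0 - 0.1 - 0.001, -100.0 - 0.001, -100.0)
        assert state.a == pytest.approx(0.01)
        assert aitken_converged(state, epsilon=0.1)

    def test_divergent_ratio_is_not_converged(self):
        assert not aitken_converged(AitkenState(-103.0, -102.0, -100.0))


class TestFitSingle:
    def test_determinism_bit_identical(self):
        ds = generate_dataset(SimulationDesign(G=2, model="CUC", seed=5))
        fits = [
            fit_single(ds.x, "CUC", 2, ds.spec, n_starts=1, seed=123)
            for _ in range(2)
        ]
        np.testing.assert_array_equal(fits[0].zhat, fits[1].zhat)
        np.testing.assert_array_equal(fits[0].loglik_trace, fits[1].loglik_trace)
        np.testing.assert_array_equal(fits[0].params.mu, fits[1].params.mu)
        np.testing.assert_array_equal(
            np.asarray(fits[0].params.psi), np.asarray(fits[1].params.psi)
        )

    def test_single_component_recovers_sample_mean(self, rng):
        ds = generate_dataset(SimulationDesign(G=2, model="CUU", seed=9))
        fit = fit_single(ds.x, "CUU", 1, ds.spec, n_starts=2, seed=1)
        assert fit.params.pi == pytest.approx([1.0])
        np.testing.assert_allclose(
            fit.params.mu[0], ds.x.values.mean(axis=0), atol=1e-8
        )

    def test_well_separated_data_perfect_recovery(self):
        ds = generate_dataset(
            SimulationDesign(G=2, case="low_var_good_sep", model="CUC", seed=17)
        )
        fit = fit_single(ds.x, "CUC", 2, ds.spec, n_starts=20, seed=3)
        assert fit.converged
        labels = map_classify(fit.zhat)
        assert adjusted_rand_index(ds.labels, labels) == 1.0

    def test_loglik_trace_nondecreasing(self):
        ds = generate_dataset(
            SimulationDesign(G=3, case="high_var_close", model="UUU", seed=2)
        )
        fit = fit_single(ds.x, "UUU", 3, ds.spec, n_starts=5, seed=4)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_mean_recovery_within_standard_errors(self):
        """Fitted means land within 3 SE of the generating means (n=200)."""
        ds = generate_dataset(
            SimulationDesign(G=2, case="low_var_good_sep", model="CUU", seed=31)
        )
        fit = fit_single(ds.x, "CUU", 2, ds.spec, n_starts=10, seed=8)
        est = map_classify(fit.zhat)
        # optimal label matching for G=2: identity or swap
        perm = (0, 1)
        if np.mean(est[ds.labels == 0] == 1) > 0.5:
            perm = (1, 0)
        for g in range(2):
            sigma = covariance_from_params(ds.params, g)
            se = np.sqrt(np.diag(sigma) / (ds.x.n / 2))
            err = np.abs(fit.params.mu[perm[g]] - ds.params.mu[g])
            assert np.all(err <= 3 * se)

    def test_row_permutation_exchangeability(self):
        """Permuting observations permutes zhat identically (matched start)."""
        from osgabi.aecm import _aecm_run

        ds = generate_dataset(SimulationDesign(G=2, model="CUC", seed=41))
        params0 = ds.params
        xv = ds.x.values
        perm = np.random.default_rng(0).permutation(xv.shape[0])
        p1, z1, t1, *_ = _aecm_run(xv, params0, 0.1, 50, 3)
        p2, z2, t2, *_ = _aecm_run(xv[perm], params0, 0.1, 50, 3)
        np.testing.assert_allclose(z1[perm], z2, atol=1e-10)
        np.testing.assert_allclose(p1.mu, p2.mu, atol=1e-10)
        np.testing.assert_allclose(t1, t2, atol=1e-8)


class TestFitGrid:
    def test_single_cell_grid_is_the_winner(self):
        ds = generate_dataset(SimulationDesign(G=2, model="CUC", seed=6))
        table, model, G = fit_grid(ds.x, ["CUC"], [2], ds.spec,
                                   n_starts=5, seed=9)
        assert (model, G) == ("CUC", 2)

    def test_same_seed_identical_selection(self):
        ds = generate_dataset(SimulationDesign(G=2, model="CUC", seed=6))
        out = [
            fit_grid(ds.x, ["CUC", "CUU"], [2, 3], ds.spec, n_starts=3, seed=9)
            for _ in range(2)
        ]
        assert out[0][1:] == out[1][1:]
        pd_eq = out[0][0].to_frame().equals(out[1][0].to_frame())
        assert pd_eq

    def test_lambda_count_pins_g_for_unconstrained_models(self):
        ds = generate_dataset(SimulationDesign(G=3, model="UUC", seed=12))
        assert len(ds.spec.matrices) == 3
        table, model, G = fit_grid(ds.x, ["UUC"], range(2, 11), ds.spec,
                                   n_starts=5, seed=2)
        # G range is ignored: the three supplied matrices imply G=3
        assert [r["G"] for r in table.rows] == [3]
        assert G == 3

    def test_empty_grid_rejected(self, canonical_spec):
        ds = generate_dataset(SimulationDesign(G=2, model="CUC", seed=6))
        with pytest.raises(ValueError):
            fit_grid(ds.x, [], [2], ds.spec)
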