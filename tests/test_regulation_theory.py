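"""Regulation-fitness theory: closed forms, their oracles, optima, phases."""

import numpy as np
import pytest
from scipy import integrate

from noisereg.regulation_theory import (
    EnvironmentEnsemble,
    RegulatorProfile,
    composite_regulator,
    coupling_state,
    dlogf,
    dlogf_constructive,
    fitness_landscape,
    iterate_regulation,
    logfitness_coupled,
    logfitness_unregulated,
    maximize_dlogf,
    mismatch_Y,
    optimal_coupling,
    optimal_sigma2_unregulated,
    optimal_signal_to_noise,
    predicted_total_noise,
    regulator_RS,
)
from noisereg.synthetic_data import gen_environment_and_regulator


def random_system(rng, allow_negative_c=True):
    n = int(rng.integers(3, 12))
    env = EnvironmentEnsemble(rng.normal(8.0, rng.uniform(0.1, 1.0), n), rng.uniform(0.02, 0.2))
    reg = RegulatorProfile(rng.normal(0.0, 1.0, n), rng.uniform(0.001, 0.1))
    sigma2 = rng.uniform(0.001, 0.05)
    lo = -2.0 if allow_negative_c else 0.05
    c = rng.uniform(lo, 2.0)
    if abs(c) < 0.05:
        c = 0.5
    return env, reg, sigma2, c


class TestMismatchAndRS:
    def test_constant_levels_have_zero_mismatch(self):
        env = EnvironmentEnsemble(np.full(4, 8.0), 0.05)
        assert mismatch_Y(env, 0.01) == 0.0

    def test_unit_mismatch_by_construction(self):
        # var(mu_e) = sigma^2 + tau^2  =>  Y = 1
        mu_e = np.array([7.9, 8.0, 8.1])
        env = EnvironmentEnsemble(mu_e, 0.05)
        s2 = env.var_mu_e - 0.05**2
        assert mismatch_Y(env, s2) == pytest.approx(1.0, rel=1e-12)

    def test_three_symmetric_environments(self):
        # mu_e = {mu-d, mu, mu+d}: Y^2 = (2 d^2 / 3) / (sigma^2 + tau^2)
        d, s2, tau = 0.5, 0.01, 0.03
        env = EnvironmentEnsemble([8 - d, 8.0, 8 + d], tau)
        expected = np.sqrt((2 * d**2 / 3) / (s2 + tau**2))
        assert mismatch_Y(env, s2) == pytest.approx(expected, rel=1e-12)

    def test_affine_regulator_is_perfectly_correlated(self):
        env = EnvironmentEnsemble([7.5, 8.0, 8.6, 9.0], 0.05)
        reg = RegulatorProfile(2.0 * env.mu_e - 3.0, 0.01)
        R, S = regulator_RS(env, reg)
        assert R == pytest.approx(1.0)

    def test_orthogonal_regulator_uncorrelated(self, rng):
        env, reg = gen_environment_and_regulator(
            np.array([7.5, 8.0, 8.5, 9.0, 9.2]), 0.05, 0.0, 2.0, rng
        )
        R, S = regulator_RS(env, reg)
        assert R == pytest.approx(0.0, abs=1e-12)

    def test_signal_to_noise_definition(self):
        env = EnvironmentEnsemble([7.0, 8.0, 9.0], 0.05)
        r_e = env.mu_e.copy()
        var_r = r_e.var()
        reg = RegulatorProfile(r_e, var_r / 4.0)  # var(r_e) = 4 sigma_r^2
        _, S = regulator_RS(env, reg)
        assert S == pytest.approx(2.0, rel=1e-12)

    def test_constant_regulator_signalled(self):
        env = EnvironmentEnsemble([7.0, 8.0, 9.0], 0.05)
        reg = RegulatorProfile(np.full(3, 1.0), 0.01)
        with pytest.warns(UserWarning, match="undefined"):
            R, S = regulator_RS(env, reg)
        assert np.isnan(R) and S == 0.0


class TestLogFitness:
    def test_perfect_promoter_has_zero_logfitness(self):
        env = EnvironmentEnsemble(np.full(3, 8.0), 0.05)
        assert logfitness_unregulated(8.0, 0.0, env) == pytest.approx(0.0, abs=1e-15)

    def test_matches_per_environment_average_of_gate_fitness(self, rng):
        # closed form equals the weighted mean over environments of
        # log of the Gaussian genotype fitness
        from noisereg.selection_sim import SelectionGate, genotype_fitness

        for _ in range(100):
            env, _, sigma2, _ = random_system(rng)
            mu = rng.normal(8.0, 0.5)
            direct = np.average(
                [
                    np.log(genotype_fitness(mu, sigma2, SelectionGate(m, env.tau)))
                    for m in env.mu_e
                ],
                weights=env.weights,
            )
            assert logfitness_unregulated(mu, sigma2, env) == pytest.approx(
                direct, abs=1e-12
            )

    def test_maximized_at_mean_desired_level(self, rng):
        env, _, sigma2, _ = random_system(rng)
        best = logfitness_unregulated(env.mean_mu_e, sigma2, env)
        for d in (-0.3, -0.01, 0.01, 0.3):
            assert logfitness_unregulated(env.mean_mu_e + d, sigma2, env) < best

    def test_gaussian_quadrature_oracle(self, rng):
        # per environment, log-fitness is the log of the integral of the
        # Gaussian fitness against the Gaussian expression distribution
        env = EnvironmentEnsemble([7.8, 8.0, 8.4], 0.1)
        mu, sigma2 = 8.05, 0.02
        per_env = []
        for m in env.mu_e:
            val, _ = integrate.quad(
                lambda x: np.exp(-((x - m) ** 2) / (2 * env.tau**2))
                * np.exp(-((x - mu) ** 2) / (2 * sigma2))
                / np.sqrt(2 * np.pi * sigma2),
                mu - 12 * np.sqrt(sigma2),
                mu + 12 * np.sqrt(sigma2),
            )
            per_env.append(np.log(val))
        assert logfitness_unregulated(mu, sigma2, env) == pytest.approx(
            np.mean(per_env), abs=1e-10
        )

    def test_coupled_reduces_to_unregulated_at_zero_coupling(self, rng):
        env, reg, sigma2, _ = random_system(rng)
        mu = 8.0
        assert logfitness_coupled(mu, sigma2, 0.0, env, reg) == pytest.approx(
            logfitness_unregulated(mu, sigma2, env), abs=1e-14
        )

    def test_perfect_tracking_limit(self):
        # an exact, noiseless condition-response leaves only the basal width
        env = EnvironmentEnsemble([7.5, 8.0, 8.5], 0.05)
        sigma2 = 0.01
        dev = env.mu_e - env.mean_mu_e
        reg = RegulatorProfile(dev, 1e-14)  # c = 1 reproduces mu_e exactly
        lf = logfitness_coupled(env.mean_mu_e, sigma2, 1.0, env, reg)
        assert lf == pytest.approx(0.5 * np.log(env.tau**2 / (env.tau**2 + sigma2)), abs=1e-9)

    def test_bet_hedging_optimum_numeric(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 10))
            env = EnvironmentEnsemble(
                rng.normal(8.0, rng.uniform(0.01, 0.5), n), rng.uniform(0.02, 0.3)
            )
            opt = optimal_sigma2_unregulated(env)
            expected = max(0.0, env.var_mu_e - env.tau**2)
            assert opt == pytest.approx(expected, abs=1e-6)


class TestDlogf:
    def test_zero_at_zero_coupling(self, rng):
        for _ in range(20):
            assert dlogf(0.0, rng.uniform(0, 5), rng.uniform(-1, 1), rng.uniform(0, 5)) == 0.0

    def test_identity_against_constructive_oracle(self, rng):
        # Eq-level identity: the 4-parameter closed form equals the
        # difference of environment-averaged coupled/unregulated log-fitness
        for _ in range(100):
            env, reg, sigma2, c = random_system(rng)
            st = coupling_state(0.0, sigma2, c, env, reg)
            assert dlogf(st.X, st.Y, st.R, st.S) == pytest.approx(
                dlogf_constructive(sigma2, c, env, reg), abs=1e-10
            )

    def test_optimal_S_closed_form(self, rng):
        # at fixed (X, Y, R) the gain is maximized at S = R Y / X
        for _ in range(50):
            X = rng.uniform(0.2, 4.0)
            Y = rng.uniform(0.2, 5.0)
            R = rng.uniform(-0.95, 0.95)
            s_star = optimal_signal_to_noise(R, Y, X)
            grid = np.linspace(s_star - 2, s_star + 2, 2001)
            vals = [dlogf(X, Y, R, s) for s in grid]
            assert grid[int(np.argmax(vals))] == pytest.approx(s_star, abs=2e-3)

    def test_optimal_S_at_zero_correlation_is_zero(self):
        assert optimal_signal_to_noise(0.0, 3.0, 1.5) == 0.0

    def test_optimal_S_hand_value(self):
        assert optimal_signal_to_noise(0.95, 4.0, 1.0) == pytest.approx(3.8)

    def test_optimal_S_undefined_at_zero_coupling(self):
        with pytest.raises(ValueError, match="X = 0"):
            optimal_signal_to_noise(0.5, 2.0, 0.0)


class TestOptimalCoupling:
    def test_perfect_regulator_needs_no_noise_propagation(self):
        assert optimal_coupling(3.0, 1.0) == 0.0
        assert optimal_coupling(0.5, 0.0) == 0.0  # (1-R^2) Y^2 <= 1

    def test_hand_values(self):
        assert optimal_coupling(2.0, 0.0) ** 2 == pytest.approx(3.0)
        # the moderately correlated worked example, R = 0.64, Y = 4
        assert optimal_coupling(4.0, 0.64) ** 2 == pytest.approx(
            (1 - 0.4096) * 16 - 1
        )

    def test_joint_numeric_optimum_lands_on_closed_form(self, rng):
        for _ in range(15):
            Y = rng.uniform(1.2, 5.0)
            R = rng.uniform(0.0, 0.9)
            val, X, S = maximize_dlogf(Y, R)
            xs = optimal_coupling(Y, R)
            assert X**2 == pytest.approx(xs**2, abs=1e-5)
            if xs**2 > 0.05:
                assert S == pytest.approx(R * Y / xs, abs=1e-5)


class TestPhaseDiagram:
    def test_basal_regime_returns_basal_noise(self):
        env = EnvironmentEnsemble([7.9, 8.0, 8.1], 0.05)
        assert predicted_total_noise(1.0, env, 0.01) == 0.01

    def test_environment_driven_hand_value(self):
        # R = 0, var(mu_e) = 10 tau^2, sigma^2 = tau^2  ->  sigma_tot^2 = 9 tau^2
        tau = 0.1
        d = np.sqrt(10 * tau**2 * 3 / 2)
        env = EnvironmentEnsemble([8 - d, 8.0, 8 + d], tau)
        assert env.var_mu_e == pytest.approx(10 * tau**2)
        assert predicted_total_noise(0.0, env, tau**2) == pytest.approx(9 * tau**2)

    def test_continuity_across_phase_boundary(self):
        # scan R through the boundary (1-R^2) Y^2 = 1 at fixed ensemble
        env = EnvironmentEnsemble([7.0, 8.0, 9.0], 0.05)
        sigma2 = 0.02
        Y2 = env.var_mu_e / (sigma2 + env.tau**2)
        r_star = np.sqrt(1 - 1 / Y2)
        lo = predicted_total_noise(r_star + 1e-9, env, sigma2)
        hi = predicted_total_noise(r_star - 1e-9, env, sigma2)
        assert lo == pytest.approx(hi, abs=1e-6)
        assert lo == pytest.approx(sigma2, abs=1e-6)

    def test_matches_explicit_coupling_optimization(self, rng):
        # optimal-coupling total variance sigma^2 + c*^2 sigma_r^2 from a
        # joint numeric (c, sigma_r) optimization of the constructive
        # log-fitness equals the phase-diagram prediction
        from scipy import optimize as opt

        for _ in range(5):
            mu_e = rng.normal(8.0, 0.6, 6)
            env, reg0 = gen_environment_and_regulator(mu_e, 0.05, 0.4, 2.0, rng)
            sigma2 = 0.01
            Y = mismatch_Y(env, sigma2)
            if (1 - 0.4**2) * Y**2 <= 1.2:
                continue  # stay clearly inside the environment-driven regime

            def neg(params):
                c, log_sr2 = params
                reg = RegulatorProfile(reg0.r_e, float(np.exp(log_sr2)))
                mean_r = float(np.sum(env.weights * reg.r_e))
                return -logfitness_coupled(env.mean_mu_e - c * mean_r, sigma2, c, env, reg)

            xs = optimal_coupling(Y, 0.4)
            s_star = 0.4 * Y / xs
            sr2_0 = reg0.r_e.var() / s_star**2
            c0 = np.sqrt(xs**2 * (sigma2 + env.tau**2) / sr2_0)
            res = opt.minimize(
                neg, [c0, np.log(sr2_0)], method="Nelder-Mead",
                options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000},
            )
            c_opt, sr2_opt = res.x[0], float(np.exp(res.x[1]))
            sigma_tot2 = sigma2 + c_opt**2 * sr2_opt
            assert sigma_tot2 == pytest.approx(
                predicted_total_noise(0.4, env, sigma2), abs=1e-6
            )

    def test_bet_hedging_limit_consistency(self):
        # R = 0: optimal coupling reproduces the unregulated noise optimum,
        # sigma^2 + c*^2 sigma_r^2 = var(mu_e) - tau^2
        env = EnvironmentEnsemble([7.0, 8.0, 9.0], 0.05)
        sigma2 = 0.02
        Y = mismatch_Y(env, sigma2)
        assert env.var_mu_e > sigma2 + env.tau**2
        xs2 = optimal_coupling(Y, 0.0) ** 2
        total = sigma2 + xs2 * (sigma2 + env.tau**2)
        assert total == pytest.approx(env.var_mu_e - env.tau**2, rel=1e-12)


class TestCompositeAndIterated:
    def test_single_regulator_identity(self):
        reg = RegulatorProfile(np.array([0.1, 0.5, 0.9]), 0.02)
        eff = composite_regulator([reg], [1.0])
        np.testing.assert_allclose(eff.r_e, reg.r_e)
        assert eff.sigma_r2 == pytest.approx(reg.sigma_r2)

    def test_independent_variances_add(self):
        r1 = RegulatorProfile(np.array([0.0, 1.0, 2.0]), 0.03)
        r2 = RegulatorProfile(np.array([2.0, 1.0, 0.0]), 0.05)
        eff = composite_regulator([r1, r2], [1.0, 1.0])
        assert eff.sigma_r2 == pytest.approx(0.08)
        np.testing.assert_allclose(eff.r_e, r1.r_e + r2.r_e)

    def test_correlated_cross_term_as_printed(self):
        # two perfectly correlated regulators, equal sigma:
        # sigma_r^2 = c1^2 s^2 + c2^2 s^2 + 2 s^2 (cross term without c_i c_j)
        s2 = 0.04
        r1 = RegulatorProfile(np.array([0.0, 1.0]), s2)
        r2 = RegulatorProfile(np.array([1.0, 0.0]), s2)
        corr = np.array([[1.0, 1.0], [1.0, 1.0]])
        c1, c2 = 2.0, 3.0
        eff = composite_regulator([r1, r2], [c1, c2], corr)
        assert eff.sigma_r2 == pytest.approx(c1**2 * s2 + c2**2 * s2 + 2 * s2)
        # coupling-weighted variant: cross term carries c1 c2
        eff2 = composite_regulator([r1, r2], [c1, c2], corr, weight_cross_by_couplings=True)
        assert eff2.sigma_r2 == pytest.approx(c1**2 * s2 + c2**2 * s2 + 2 * c1 * c2 * s2)

    def test_non_psd_correlation_rejected(self):
        r = RegulatorProfile(np.array([0.0, 1.0]), 0.01)
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="semidefinite"):
            composite_regulator([r, r], [1.0, 1.0], bad)

    def test_iterate_zero_coupling_is_identity(self):
        env = EnvironmentEnsemble([7.5, 8.0, 8.5], 0.05)
        reg = RegulatorProfile(np.array([0.0, 0.5, 1.0]), 0.01)
        sigma2 = 0.02
        res = iterate_regulation(env, reg, 0.0, sigma2)
        np.testing.assert_allclose(res.mu_e_residual, env.mu_e)
        assert res.sigma2_new == sigma2
        assert res.Y_new == pytest.approx(mismatch_Y(env, sigma2))

    def test_perfect_tracking_removes_mismatch(self):
        env = EnvironmentEnsemble([7.5, 8.0, 8.5], 0.05)
        reg = RegulatorProfile(env.mu_e.copy(), 1e-8)
        res = iterate_regulation(env, reg, 1.0, 0.02)
        assert np.allclose(res.mu_e_residual, res.mu_e_residual[0])
        assert res.Y_new == pytest.approx(0.0, abs=1e-12)

    def test_residual_mismatch_matches_direct_recomputation(self, rng):
        env, reg, sigma2, c = random_system(rng)
        res = iterate_regulation(env, reg, c, sigma2)
        resid = env.mu_e - c * reg.r_e
        var_res = float(np.sum(env.weights * (resid - np.sum(env.weights * resid)) ** 2))
        expected = np.sqrt(var_res / (sigma2 + c**2 * reg.sigma_r2 + env.tau**2))
        assert res.Y_new == pytest.approx(expected, rel=1e-12)


class TestLandscape:
    def test_zero_correlation_column_against_direct_formula(self):
        # R = 0: cell value is max_X [ X^2 (Y^2 - S^2) / (2 (1+X^2))
        #                              - log(1+X^2)/2 ]
        from scipy.optimize import minimize_scalar

        Y = 3.0
        S_grid = [0.0, 1.0, 2.0, 4.0]
        gain, _ = fitness_landscape(Y, [0.0], S_grid)
        for j, S in enumerate(S_grid):
            ref = -minimize_scalar(
                lambda X: -(0.5 * X**2 * (Y**2 - S**2) / (1 + X**2) - 0.5 * np.log1p(X**2)),
                bounds=(0, 20.0), method="bounded", options={"xatol": 1e-10},
            ).fun
            ref = max(ref, 0.0)
            assert gain[0, j] == pytest.approx(ref, abs=1e-6)

    def test_monotone_in_R_below_the_ridge(self):
        # at fixed S on the sub-ridge side, better-correlated regulators win
        Y = 4.0
        R_grid = np.linspace(0.0, 0.9, 10)
        gain, ridge = fitness_landscape(Y, R_grid, [1.0])
        assert np.all(np.diff(gain[:, 0]) >= -1e-9)

    def test_ridge_curve_matches_closed_form(self):
        Y = 4.0
        R_grid = np.array([0.0, 0.3, 0.6])
        _, ridge = fitness_landscape(Y, R_grid, [1.0])
        for r, s in zip(R_grid, ridge):
            xs = optimal_coupling(Y, r)
            assert s == pytest.approx(r * Y / xs if xs > 0 else np.nan, nan_ok=True)

    def test_perfect_tracking_gain_from_constructive_path(self):
        # at R = 1 the full mismatch is recoverable: the coupled log-fitness
        # in the noiseless-regulator limit exceeds the unregulated one by
        # Y^2/2 (Eq-level X->0, S->inf ordering handled constructively)
        env = EnvironmentEnsemble([7.0, 8.0, 9.0], 0.05)
        sigma2 = 0.02
        Y = mismatch_Y(env, sigma2)
        dev = env.mu_e - env.mean_mu_e
        reg = RegulatorProfile(dev, 1e-16)
        gain = logfitness_coupled(env.mean_mu_e, sigma2, 1.0, env, reg) - \
            logfitness_unregulated(env.mean_mu_e, sigma2, env)
        assert gain == pytest.approx(0.5 * Y**2, rel=1e-6)
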