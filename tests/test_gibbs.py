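"""Gibbs sampler: conditional correctness, reproducibility, invariances."""

import numpy as np
import pytest

from fwreg import (
    CovarianceSpec,
    GibbsConfig,
    Hyperparameters,
    PhenotypeTable,
    SampleStore,
    default_hyperparameters,
    gibbs_cycle,
    run_gibbs,
    simulate_fw_table,
    timeseries_se,
    validate_and_align,
)
from fwreg.gibbs import draw_coefficient_block, draw_variance


class TestDefaultHyperparameters:
    def test_variance_partition_rule(self):
        """With Var(y)=1 and df=5 everywhere: S2_e = 0.5*3/5 = 0.3 and
        S2_g = S2_b = 0.25*3/5 = 0.15."""
        a = np.sqrt(0.5)
        y = np.array([a, -a])  # sample variance exactly 1
        hp = default_hyperparameters(y)
        assert hp.df_e == hp.df_g == hp.df_b == hp.df_h == 5.0
        assert hp.S2_e == pytest.approx(0.3)
        assert hp.S2_g == pytest.approx(0.15)
        assert hp.S2_b == pytest.approx(0.15)
        assert hp.S2_h == pytest.approx(0.3)
        # prior expectations partition Var(y)
        assert hp.prior_mean("e") == pytest.approx(0.5)
        assert hp.prior_mean("g") + hp.prior_mean("b") == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            default_hyperparameters(np.ones(10))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            default_hyperparameters(np.array([1.0]))

    def test_df_two_accepted_with_warning(self):
        with pytest.warns(UserWarning, match="no finite mean"):
            hp = Hyperparameters(df_e=2.0, S2_e=1.0, df_g=5, S2_g=1,
                                 df_b=5, S2_b=1, df_h=5, S2_h=1)
        assert np.isinf(hp.prior_mean("e"))

    def test_user_hyperparameters_pass_through(self, toy_2x2):
        hp = Hyperparameters(df_e=4, S2_e=0.2, df_g=6, S2_g=0.1,
                             df_b=6, S2_b=0.1, df_h=7, S2_h=0.3)
        fit, _ = run_gibbs(toy_2x2, hyper=hp,
                           config=GibbsConfig(n_iter=50, burn_in=10, seed=0))
        assert fit.method == "Gibbs"  # accepted unchanged, sampler ran


class TestConditionals:
    N_DRAWS = 100_000

    def test_variance_conditional_zero_vector_case(self):
        """u = 0, K = I, q = 3, df = 4, S2 = 1 -> ScaledInv-chi2(7, 4/7)
        with mean 7*(4/7)/5 = 0.8."""
        rng = np.random.default_rng(42)
        draws = np.array([
            draw_variance(0.0, 3, 4.0, 1.0, rng) for _ in range(self.N_DRAWS)
        ])
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - 0.8) < 3 * se

    def test_variance_conditional_general_case(self):
        """Nonzero quadratic form: mean (quad + df*S2)/(df + q - 2)."""
        rng = np.random.default_rng(43)
        quad, q, df, s2 = 2.5, 5, 6.0, 0.4
        draws = np.array([
            draw_variance(quad, q, df, s2, rng) for _ in range(self.N_DRAWS)
        ])
        expected = (quad + df * s2) / (df + q - 2.0)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 3 * se

    @pytest.mark.parametrize("use_K", [False, True])
    def test_coefficient_block_matches_conjugate_ridge_posterior(self, use_K):
        """With the other blocks held fixed the conditional of g is the
        closed-form ridge posterior N((D/ve + K^-1/vg)^-1 r/ve, (..)^-1),
        for both the diagonal (K=I) and the dense path."""
        rng = np.random.default_rng(7)
        q = 3
        D = np.array([4.0, 2.0, 6.0])
        r = np.array([1.0, -2.0, 0.5])
        var_u, var_e = 0.5, 0.3
        if use_K:
            M = rng.normal(size=(q, q))
            K = M @ M.T + q * np.eye(q)
            K_inv = np.linalg.inv(K)
        else:
            K_inv = None
        P = np.diag(D / var_e) + (
            K_inv / var_u if use_K else np.eye(q) / var_u
        )
        cov = np.linalg.inv(P)
        mean = cov @ (r / var_e)
        draws = np.array([
            draw_coefficient_block(r, D, K_inv, var_u, var_e, rng)
            for _ in range(self.N_DRAWS)
        ])
        n = len(draws)
        for k in range(q):
            se_mean = np.sqrt(cov[k, k] / n)
            assert abs(draws[:, k].mean() - mean[k]) < 3 * se_mean
            se_var = cov[k, k] * np.sqrt(2.0 / (n - 1))
            assert abs(draws[:, k].var(ddof=1) - cov[k, k]) < 3 * se_var

    def test_prior_only_limit_when_all_y_missing(self):
        """With every phenotype missing the chain samples the prior: the
        long-run mean of the var_g draws is df*S2/(df-2)."""
        t = PhenotypeTable(
            ["L1", "L2", "L3"] * 2, ["E1"] * 3 + ["E2"] * 3, [np.nan] * 6
        )
        frame = validate_and_align(t)
        hp = Hyperparameters(df_e=6, S2_e=1.0, df_g=6, S2_g=1.0,
                             df_b=6, S2_b=1.0, df_h=6, S2_h=1.0)
        from fwreg.gibbs import _initial_state

        rng = np.random.default_rng(0)
        state = _initial_state(frame, hp)
        draws = np.empty(30_000)
        for i in range(len(draws)):
            state = gibbs_cycle(state, frame, None, None, hp, rng)
            draws[i] = state.var_g
        expected = 6 * 1.0 / 4.0
        assert abs(draws.mean() - expected) < 3 * timeseries_se(draws)


class TestRunGibbs:
    def small_table(self, seed=0):
        table, _ = simulate_fw_table(n_lines=12, n_envs=3, seed=seed)
        return table

    def test_same_seed_bit_identical(self):
        t = self.small_table()
        cfg = GibbsConfig(n_iter=300, burn_in=100, thin=2, seed=99)
        fit1, st1 = run_gibbs(t, config=cfg)
        fit2, st2 = run_gibbs(t, config=cfg)
        for a, b in zip(st1.chains, st2.chains):
            assert a.equals(b)
        np.testing.assert_array_equal(fit1.yhat, fit2.yhat)
        np.testing.assert_array_equal(fit1.g, fit2.g)
        np.testing.assert_array_equal(fit1.var_h, fit2.var_h)

    def test_chain_count_and_store_length(self):
        t = self.small_table()
        cfg = GibbsConfig(n_iter=230, burn_in=30, thin=7, n_chains=3, seed=5)
        fit, store = run_gibbs(t, config=cfg)
        assert len(store) == 3
        assert all(len(c) == (230 - 30) // 7 for c in store.chains)
        assert fit.g.shape == (12, 3)
        for chain in store.chains:
            for col in ("var_e", "var_g", "var_b", "var_h"):
                assert (chain[col] > 0).all()

    def test_chains_differ_from_each_other(self):
        t = self.small_table()
        cfg = GibbsConfig(n_iter=200, burn_in=50, n_chains=2, seed=5)
        _, store = run_gibbs(t, config=cfg)
        assert not store.chains[0].equals(store.chains[1])

    def test_store_write_read_round_trip(self, tmp_path):
        t = self.small_table()
        cfg = GibbsConfig(n_iter=120, burn_in=20, seed=1,
                          save_at=str(tmp_path / "run_"))
        _, store = run_gibbs(t, config=cfg)
        back = SampleStore.read(str(tmp_path / "run_"))
        assert back.config.n_iter == 120
        np.testing.assert_allclose(
            back.chains[0].to_numpy(), store.chains[0].to_numpy()
        )
        assert list(back.chains[0].columns) == list(store.chains[0].columns)

    def test_relabeling_with_matching_A_is_exact_equivariance(self):
        """Renaming varieties (and presenting A in any label order) must not
        change the computation at all: posterior means map through the
        renaming bit for bit."""
        table, _ = simulate_fw_table(n_lines=8, n_envs=3, seed=3)
        rng = np.random.default_rng(12)
        M = rng.normal(size=(8, 8))
        K = M @ M.T / 8 + np.eye(8)
        A = CovarianceSpec([f"L{i + 1}" for i in range(8)], K)
        cfg = GibbsConfig(n_iter=200, burn_in=50, seed=4)
        fit1, _ = run_gibbs(table, A=A, config=cfg)

        renamed = PhenotypeTable(
            ["X" + v for v in table.var], table.env, table.y
        )
        perm = rng.permutation(8)
        A2 = CovarianceSpec(
            ["X" + A.labels[i] for i in perm], K[np.ix_(perm, perm)]
        )
        fit2, _ = run_gibbs(renamed, A=A2, config=cfg)
        np.testing.assert_array_equal(fit1.g, fit2.g)
        np.testing.assert_array_equal(fit1.b, fit2.b)
        np.testing.assert_array_equal(fit1.var_g, fit2.var_g)

    def test_explicit_identity_A_matches_implicit_identity(self):
        """Passing A = I through the dense matrix path gives the same
        posterior as the no-matrix (independent priors) path within Monte
        Carlo error."""
        table, _ = simulate_fw_table(n_lines=10, n_envs=4, seed=6)
        cfg = GibbsConfig(n_iter=4000, burn_in=1000, seed=11)
        fit_imp, st_imp = run_gibbs(table, config=cfg)
        A = CovarianceSpec([f"L{i + 1}" for i in range(10)], np.eye(10))
        fit_exp, st_exp = run_gibbs(table, A=A, config=cfg)
        for col in ("var_e", "var_g", "var_b", "mu"):
            a = st_imp.chains[0][col].to_numpy()
            b = st_exp.chains[0][col].to_numpy()
            tol = 3 * (timeseries_se(a) + timeseries_se(b))
            assert abs(a.mean() - b.mean()) < tol, col

    def test_missing_records_do_not_perturb_the_chain(self):
        """Appending missing-phenotype records leaves every draw identical
        (they enter no likelihood sum) while still receiving predictions."""
        t = self.small_table()
        extra = PhenotypeTable(
            list(t.var) + ["L1", "L5"],
            list(t.env) + ["E2", "E3"],
            list(t.y) + [np.nan, np.nan],
        )
        cfg = GibbsConfig(n_iter=200, burn_in=50, seed=8)
        fit1, st1 = run_gibbs(t, config=cfg)
        fit2, st2 = run_gibbs(extra, config=cfg)
        assert st1.chains[0].equals(st2.chains[0])
        assert fit2.yhat.shape[0] == len(t) + 2
        assert np.isfinite(fit2.yhat).all()

    def test_all_missing_environment_prior_centered_without_H(self):
        """An environment with no data and identity H has posterior h
        centered at zero (within two posterior SDs)."""
        table, _ = simulate_fw_table(n_lines=30, n_envs=3, seed=10)
        y = table.y.copy()
        y[np.asarray(table.env) == "E3"] = np.nan
        masked = PhenotypeTable(table.var, table.env, y)
        fit, _ = run_gibbs(
            masked, config=GibbsConfig(n_iter=2000, burn_in=500, seed=2)
        )
        j = fit.environments.index("E3")
        assert abs(fit.h[j, 0]) < 2 * fit.sd_h[j, 0]

    def test_posterior_predictor_converges_to_cell_means(self):
        """With 200 replicates per cell the posterior mean of
        mu + g_i + (1+b_i)h_j approaches each cell mean."""
        table, truth = simulate_fw_table(
            n_lines=3, n_envs=2, var_e=0.25, replicates=200, seed=13
        )
        fit, _ = run_gibbs(
            table, config=GibbsConfig(n_iter=2000, burn_in=500, seed=14)
        )
        df = table.to_frame()
        df["yhat"] = fit.yhat[:, 0]
        cells = df.groupby(["VAR", "ENV"], sort=False).mean()
        se = np.sqrt(0.25 / 200)
        np.testing.assert_allclose(
            cells["yhat"], cells["y"], atol=3 * se
        )

    def test_config_validation(self):
        with pytest.raises(ValueError, match="burn_in"):
            GibbsConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError, match="thin"):
            GibbsConfig(thin=0)
        with pytest.raises(ValueError, match="n_chains"):
            GibbsConfig(n_chains=0)

    def test_unknown_monitor_label_rejected_before_sampling(self):
        t = self.small_table()
        cfg = GibbsConfig(n_iter=100, burn_in=10, save_varieties=["nope"])
        with pytest.raises(ValueError, match="nope"):
            run_gibbs(t, config=cfg)
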