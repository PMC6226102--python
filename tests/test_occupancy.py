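"""Occupancy model: closed-form likelihood vs enumeration, sampler
behaviour, convergence diagnostics, and posterior summaries."""

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_cell_loglik, sorted_order_quantiles
from batscape.landscape import standardize
from batscape.occupancy import (
    DegenerateChainsError,
    McmcConfig,
    ModelSpec,
    fit_mcmc,
    marginal_cell_loglik,
    prepare_data,
    rhat,
    summarize_posterior,
)


class TestMarginalLoglik:
    def test_all_zero_history_mixes_both_states(self):
        # psi q1 + (1 - psi): 0.5*0.25 + 0.5 = 0.625
        ll = marginal_cell_loglik([[0, 0]], [[0.5, 0.5]], psi1=0.5)
        assert np.exp(ll) == pytest.approx(0.625)

    def test_detection_forces_occupied_state(self):
        ll = marginal_cell_loglik([[1, 0]], [[0.5, 0.5]], psi1=0.5)
        assert np.exp(ll) == pytest.approx(0.125)

    def test_matches_enumeration_on_random_instances(self, rng):
        for _ in range(300):
            T = int(rng.integers(1, 4))
            ys, ps = [], []
            occupied = rng.random() < 0.5
            for _t in range(T):
                J = int(rng.integers(0, 5))
                p = rng.uniform(0.05, 0.95, J)
                y = (rng.random(J) < 0.4).astype(int) if occupied else np.zeros(J, int)
                ys.append(y)
                ps.append(p)
            psi1, g, e = rng.uniform(0.01, 0.99, 3)
            assert marginal_cell_loglik(ys, ps, psi1, g, e) == pytest.approx(
                brute_force_cell_loglik(ys, ps, psi1, g, e), abs=1e-12)

    def test_frozen_dynamics_pool_years(self, rng):
        # gamma = eps = 0: both years share one latent state, so the
        # two-year likelihood equals the pooled one-year history
        y1, y2 = [0, 1, 0], [1, 0]
        p1, p2 = [0.3, 0.6, 0.2], [0.5, 0.4]
        two_year = marginal_cell_loglik([y1, y2], [p1, p2], 0.4, 0.0, 0.0)
        pooled = marginal_cell_loglik([y1 + y2], [p1 + p2], 0.4)
        assert two_year == pytest.approx(pooled, abs=1e-12)

    def test_missing_probability_errors(self):
        with pytest.raises(ValueError, match="missing"):
            marginal_cell_loglik([[0, 1]], [[0.4, np.nan]], 0.5)

    def test_grid_search_recovers_generating_psi_p(self):
        # expected log-likelihood (exact history weights) peaks at the truth
        psi_true, p_true, J = 0.6, 0.35, 4
        histories = [np.array(list(np.binary_repr(h, J)), dtype=int) for h in range(2 ** J)]
        weights = []
        for y in histories:
            w = psi_true * np.prod(np.where(y == 1, p_true, 1 - p_true))
            if not y.any():
                w += 1 - psi_true
            weights.append(w)
        grid = np.arange(0.01, 1.0, 0.01)
        best, best_val = None, -np.inf
        for psi in grid:
            for p in grid:
                val = sum(
                    w * marginal_cell_loglik([y], [np.full(J, p)], psi)
                    for w, y in zip(weights, histories))
                if val > best_val:
                    best, best_val = (psi, p), val
        assert best[0] == pytest.approx(psi_true, abs=0.011)
        assert best[1] == pytest.approx(p_true, abs=0.011)

    def test_cell_label_exchangeability(self, small_study, tiny_mcmc):
        # duplicating a cell's rows under a new label doubles nothing:
        # identical cells contribute identical marginal likelihoods
        det = small_study["detections"]
        cov_std, _ = standardize(small_study["covariates"])
        spec = ModelSpec("m", occupancy=("Forest",), detection=("duration",))
        data = prepare_data(det, cov_std, spec)
        from batscape.occupancy import pointwise_loglik

        beta = np.array([[0.2, 0.5]])
        alpha = np.array([[0.1, 0.3]])
        ll = pointwise_loglik(data, beta, alpha, np.array([0.3]), np.array([0.2]))
        first = det["cell_id"].iloc[0]
        clone = det[det["cell_id"] == first].assign(cell_id="zzz_clone")
        cov_clone = pd.concat([
            cov_std, cov_std[cov_std["cell_id"] == first].assign(cell_id="zzz_clone")])
        data2 = prepare_data(pd.concat([det, clone]), cov_clone, spec)
        ll2 = pointwise_loglik(data2, beta, alpha, np.array([0.3]), np.array([0.2]))
        i = data.cells.index(first)
        assert ll2[0, -1] == pytest.approx(ll[0, i], abs=1e-12)


class TestPrepareData:
    def test_unknown_covariate_listed(self, small_study):
        cov_std, _ = standardize(small_study["covariates"])
        spec = ModelSpec("m", occupancy=("Elevation",))
        with pytest.raises(KeyError, match="Elevation"):
            prepare_data(small_study["detections"], cov_std, spec)

    def test_missing_detection_covariate_value_errors(self, small_study):
        det = small_study["detections"].copy()
        det.loc[det.index[3], "duration"] = np.nan
        cov_std, _ = standardize(small_study["covariates"])
        spec = ModelSpec("m", detection=("duration",))
        with pytest.raises(ValueError, match="duration"):
            prepare_data(det, cov_std, spec)

    def test_region_dummies_use_alphabetical_reference(self, small_study):
        cov_std, _ = standardize(small_study["covariates"])
        spec = ModelSpec("m", occupancy=("Region",))
        data = prepare_data(small_study["detections"], cov_std, spec)
        assert "psi:Region[Blue Ridge]" not in data.beta_names
        assert sum(n.startswith("psi:Region[") for n in data.beta_names) == 4


class TestSampler:
    def test_same_seed_identical_draws(self, small_study):
        cov_std, _ = standardize(small_study["covariates"])
        spec = ModelSpec("m", occupancy=("Forest",), detection=("duration",))
        config = McmcConfig(n_chains=2, n_burnin=100, n_sampling=200, thin=4, seed=3)
        a = fit_mcmc(small_study["detections"], cov_std, spec, config)
        b = fit_mcmc(small_study["detections"], cov_std, spec, config)
        assert (a.beta == b.beta).all()
        assert (a.alpha == b.alpha).all()
        assert (a.gamma == b.gamma).all()
        assert (a.z == b.z).all()

    def test_retained_draw_accounting(self, fitted_draws, tiny_mcmc):
        assert fitted_draws.beta.shape[:2] == (tiny_mcmc.n_chains,
                                               tiny_mcmc.retained_per_chain)
        assert fitted_draws.loglik.shape[0] == tiny_mcmc.retained_total

    def test_z_forced_one_at_detections(self, fitted_draws):
        detected = fitted_draws.data.detected
        z = fitted_draws.z  # (chains, draws, cells, years)
        assert (z[:, :, detected] == 1).all()

    def test_gamma_epsilon_in_unit_interval(self, fitted_draws):
        assert ((fitted_draws.gamma >= 0) & (fitted_draws.gamma <= 1)).all()
        assert ((fitted_draws.epsilon >= 0) & (fitted_draws.epsilon <= 1)).all()

    def test_distinct_seeds_distinct_draws(self, small_study):
        cov_std, _ = standardize(small_study["covariates"])
        spec = ModelSpec("m", occupancy=(), detection=())
        c1 = McmcConfig(n_chains=2, n_burnin=50, n_sampling=100, thin=2, seed=1)
        c2 = McmcConfig(n_chains=2, n_burnin=50, n_sampling=100, thin=2, seed=2)
        a = fit_mcmc(small_study["detections"], cov_std, spec, c1)
        b = fit_mcmc(small_study["detections"], cov_std, spec, c2)
        assert not np.array_equal(a.beta, b.beta)


class TestRhat:
    def test_iid_chains_near_one(self):
        g = np.random.default_rng(0)
        chains = g.normal(size=(3, 10_000))
        assert 0.99 <= rhat(chains) <= 1.02

    def test_separated_chains_flagged(self):
        g = np.random.default_rng(1)
        chains = np.stack([g.normal(0, 1, 1000), g.normal(10, 1, 1000)])
        assert rhat(chains) > 1.1 * 5

    def test_constant_chains_degenerate(self):
        with pytest.raises(DegenerateChainsError):
            rhat(np.ones((3, 100)))

    def test_formula_by_hand(self):
        chains = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]])
        m, n = chains.shape
        W = np.mean([np.var(c, ddof=1) for c in chains])
        B = n * np.var([c.mean() for c in chains], ddof=1)
        expected = np.sqrt(((n - 1) / n * W + B / n) / W)
        assert rhat(chains) == pytest.approx(expected, abs=1e-15)


class TestSummaries:
    def test_quantiles_match_order_statistic_oracle(self, rng):
        draws = rng.normal(size=40)
        lo, hi = sorted_order_quantiles(draws)
        q = np.quantile(draws, [0.025, 0.975])
        assert q[0] == pytest.approx(lo, abs=1e-12)
        assert q[1] == pytest.approx(hi, abs=1e-12)

    def test_significance_rule(self, fitted_draws):
        summary = summarize_posterior(fitted_draws)
        for _, row in summary.table.iterrows():
            assert row["significant"] == (row["lo"] > 0 or row["hi"] < 0)
            assert row["lo"] <= row["hi"]

    def test_mean_psi_is_probability(self, fitted_draws):
        summary = summarize_posterior(fitted_draws)
        psi = summary.mean_psi_by_year
        assert len(psi) == 2
        assert psi[["mean", "lo", "hi"]].stack().between(0, 1).all()

    def test_forest_effect_recovered_on_small_study(self, fitted_draws, small_study):
        # generating slope 0.9 on standardized forest cover: the short fit
        # should at least find a positive posterior mean
        summary = summarize_posterior(fitted_draws)
        assert summary.table.loc["psi:Forest", "mean"] > 0


class TestConfigValidation:
    def test_default_schedule_retains_18750(self):
        config = McmcConfig()
        assert config.retained_per_chain == 6_250
        assert config.retained_total == 18_750

    def test_thin_must_divide_sampling(self):
        with pytest.raises(ValueError):
            McmcConfig(n_sampling=1001, thin=4)
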