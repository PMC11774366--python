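"""BYM model: likelihood, CAR conditionals, Gibbs updates, fitting, summaries."""

import numpy as np
import pytest
from scipy import stats

import maupbym as m
from maupbym.bym import (
    BYMError,
    car_conditional,
    gibbs_update_sigma2_u,
    gibbs_update_sigma2_v,
    log_likelihood,
)

from conftest import random_adjacency


def _state(n, alpha=0.0, beta=None, u=None, v=None, s2u=1.0, s2v=1.0):
    return m.ModelState(
        alpha=alpha,
        beta=np.zeros(0) if beta is None else np.asarray(beta, float),
        u=np.zeros(n) if u is None else np.asarray(u, float),
        v=np.zeros(n) if v is None else np.asarray(v, float),
        sigma2_u=s2u, sigma2_v=s2v,
    )


class TestLogLikelihood:
    def test_zero_mu_closed_form(self):
        y = np.array([3.0, 1.0, 0.0])
        E = y.copy() + np.array([0.0, 0.0, 2.0])
        from scipy.special import gammaln

        expected = np.sum(y * np.log(E) - E - gammaln(y + 1))
        assert log_likelihood(_state(3), y, E) == pytest.approx(expected, abs=1e-12)

    def test_single_area_hand_value(self):
        # y=2, E=1, mu=0: log(e^-1 * 1^2 / 2!) = -1 - log 2
        got = log_likelihood(_state(1), np.array([2.0]), np.array([1.0]))
        assert got == pytest.approx(-1.0 - np.log(2.0), abs=1e-12)

    def test_matches_poisson_logpmf_oracle_on_random_states(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 15))
            y = rng.poisson(4, n).astype(float)
            E = rng.lognormal(0.5, 0.4, n)
            x = rng.integers(0, 2, size=(n, 4)).astype(float)
            st_ = _state(n, alpha=rng.normal(), beta=rng.normal(0, 0.3, 4),
                         u=rng.normal(0, 0.5, n), v=rng.normal(0, 0.2, n))
            lam = E * np.exp(st_.mu(x))
            oracle = stats.poisson.logpmf(y, lam).sum()
            assert log_likelihood(st_, y, E, x) == pytest.approx(oracle, abs=1e-10)

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(BYMError):
            log_likelihood(_state(1), np.array([1.0]), np.array([0.0]))


class TestCarConditional:
    def test_unit_neighbours(self):
        adj = m.build_adjacency(["a", "b", "c"], edge_list=[("a", "b"), ("a", "c")])
        mean, var = car_conditional(np.array([9.0, 1.0, 1.0]), 0, adj, 2.0)
        assert mean == pytest.approx(1.0)
        assert var == pytest.approx(1.0)

    def test_zero_neighbours_three_of_them(self):
        adj = m.build_adjacency(
            ["a", "b", "c", "d"],
            edge_list=[("a", "b"), ("a", "c"), ("a", "d")],
        )
        mean, var = car_conditional(np.array([5.0, 0.0, 0.0, 0.0]), 0, adj, 3.0)
        assert mean == pytest.approx(0.0)
        assert var == pytest.approx(1.0)

    def test_matches_dense_evaluation_on_random_graph(self, rng):
        adj = random_adjacency(6, rng, p_edge=0.5)
        u = rng.normal(size=6)
        w = adj.weights.toarray()
        for i in range(6):
            if w[i].sum() == 0:
                continue
            mean, var = car_conditional(u, i, adj, 1.7)
            assert mean == pytest.approx((w[i] @ u) / w[i].sum(), abs=1e-12)
            assert var == pytest.approx(1.7 / w[i].sum(), abs=1e-12)

    def test_isolated_area_rejected(self):
        with pytest.warns(UserWarning):
            adj = m.build_adjacency(["a", "b", "c"], edge_list=[("a", "b")])
        with pytest.raises(BYMError):
            car_conditional(np.zeros(3), 2, adj, 1.0)


class TestGibbsVarianceUpdates:
    def test_sigma2_v_zero_vector_posterior_moments(self):
        # v = 0, n = 10, a = 1, b = 0.01 -> IG(6, 0.01), mean 0.01/5
        rng = np.random.default_rng(1)
        draws = np.array([
            gibbs_update_sigma2_v(np.zeros(10), 1.0, 0.01, rng)
            for _ in range(100_000)
        ])
        assert abs(draws.mean() - 0.002) / 0.002 < 0.05

    def test_sigma2_v_distribution_matches_inverse_gamma(self):
        rng = np.random.default_rng(2)
        v = np.array([0.1, -0.2, 0.05])
        a_post = 1.0 + 1.5
        b_post = 0.01 + 0.5 * float(v @ v)
        draws = np.array([
            gibbs_update_sigma2_v(v, 1.0, 0.01, rng) for _ in range(20_000)
        ])
        p = stats.kstest(draws, stats.invgamma(a_post, scale=b_post).cdf).pvalue
        assert p > 0.01

    def test_sigma2_v_reproducible_under_fixed_seed(self):
        d1 = gibbs_update_sigma2_v(np.ones(4), 1.0, 0.01, np.random.default_rng(7))
        d2 = gibbs_update_sigma2_v(np.ones(4), 1.0, 0.01, np.random.default_rng(7))
        assert d1 == d2

    def test_sigma2_u_constant_per_component_keeps_prior_scale(self):
        # two disconnected edges; u constant within components -> pairsum 0,
        # so the draw is IG(a + (n-c)/2, b) = IG(2, 0.01)
        with pytest.warns(UserWarning):
            adj = m.build_adjacency(["a", "b", "c", "d", "e"],
                                    edge_list=[("a", "b"), ("c", "d")])
        u = np.array([3.0, 3.0, -1.0, -1.0, 0.0])
        rng = np.random.default_rng(3)
        draws = np.array([
            gibbs_update_sigma2_u(u, adj, 1.0, 0.01, rng) for _ in range(20_000)
        ])
        p = stats.kstest(draws, stats.invgamma(2.0, scale=0.01).cdf).pvalue
        assert p > 0.01

    def test_sigma2_u_path_graph_hand_scale(self):
        # path a-b-c with u = (-1, 0, 1): pairwise sum (u_a-u_b)^2+(u_b-u_c)^2 = 2
        adj = m.build_adjacency(["a", "b", "c"], edge_list=[("a", "b"), ("b", "c")])
        u = np.array([-1.0, 0.0, 1.0])
        rng = np.random.default_rng(4)
        draws = np.array([
            gibbs_update_sigma2_u(u, adj, 1.0, 0.01, rng) for _ in range(20_000)
        ])
        # shape 1 + (3-1)/2 = 2, scale 0.01 + 1
        p = stats.kstest(draws, stats.invgamma(2.0, scale=1.01).cdf).pvalue
        assert p > 0.01


class TestFitBym:
    def test_same_seed_identical_chains(self, fitted_chain):
        outcome, cov, adj, chain = fitted_chain
        again = m.fit_bym(outcome, cov, adj, chain.config)
        assert np.array_equal(chain.alpha, again.alpha)
        assert np.array_equal(chain.u, again.u)
        assert np.array_equal(chain.sigma2_u, again.sigma2_u)

    def test_sum_to_zero_constraint_every_draw(self, fitted_chain):
        _, _, adj, chain = fitted_chain
        for c in range(adj.n_components):
            mask = adj.components == c
            assert np.abs(chain.u[:, mask].sum(axis=1)).max() < 1e-10

    def test_acceptance_rates_near_target(self, fitted_chain):
        _, _, _, chain = fitted_chain
        assert 0.25 < chain.acceptance["u_mean"] < 0.65
        assert 0.25 < chain.acceptance["alpha"] < 0.65

    def test_intercept_only_matches_poisson_glm_oracle(self, small_scenario):
        # with u and v pinned at zero the model is y ~ Poisson(E e^alpha)
        # under a flat prior, so E[e^alpha | y] ~= sum(y)/sum(E)
        data = small_scenario
        keep = data.outcomes["s1"].E > 0
        outcome = data.outcomes["s1"].subset(keep)
        adj = data.adjacency["s1"].subset(keep)
        cfg = m.BYMConfig(
            n_iter=8000, n_burnin=2000, thin=2, seed=5,
            include_covariate=False,
            update_u=False, update_v=False, update_variances=False,
        )
        chain = m.fit_bym(outcome, None, adj, cfg)
        ratio = np.round(outcome.y).sum() / outcome.E.sum()
        mc_se = 3 / np.sqrt(np.round(outcome.y).sum())
        assert abs(np.exp(chain.alpha).mean() - ratio) < mc_se * ratio

    def test_shrinkage_limit_fitted_sir_approaches_global_ratio(self, small_scenario):
        # with both variance components frozen near zero the random effects
        # cannot move, so every fitted SIR collapses to sum(y)/sum(E)
        data = small_scenario
        keep = data.outcomes["s1"].E > 0
        outcome = data.outcomes["s1"].subset(keep)
        adj = data.adjacency["s1"].subset(keep)
        cfg = m.BYMConfig(
            n_iter=4000, n_burnin=1000, thin=2, seed=6,
            include_covariate=False, update_variances=False,
            sigma2_u_init=1e-8, sigma2_v_init=1e-8,
        )
        chain = m.fit_bym(outcome, None, adj, cfg)
        summary = m.summarise(chain)
        ratio = np.round(outcome.y).sum() / outcome.E.sum()
        assert np.abs(summary.fitted_sir - ratio).max() < 0.05

    def test_fractional_counts_round_policy_warns(self, small_scenario):
        data = small_scenario
        keep = data.outcomes["m"].E > 0
        outcome = data.outcomes["m"].subset(keep)
        assert np.any(outcome.y != np.round(outcome.y))  # disaggregated
        adj = data.adjacency["m"].subset(keep)
        cfg = m.BYMConfig(n_iter=300, n_burnin=100, thin=1, seed=1,
                          include_covariate=False)
        with pytest.warns(UserWarning, match="rounded fractional"):
            chain = m.fit_bym(outcome, None, adj, cfg)
        assert chain.rounding_discrepancy > 0

    def test_zero_expected_count_rejected(self):
        adj = m.build_adjacency(["a", "b", "c"],
                                edge_list=[("a", "b"), ("b", "c")])
        outcome = m.OutcomeTable(["a", "b", "c"], [1.0, 0.0, 2.0], [1.0, 0.0, 1.0])
        with pytest.raises(BYMError, match="zero expected"):
            m.fit_bym(outcome, None, adj, m.BYMConfig(n_iter=10, n_burnin=1))

    def test_config_validation(self):
        with pytest.raises(BYMError):
            m.BYMConfig(n_iter=10, n_burnin=20)
        with pytest.raises(BYMError):
            m.BYMConfig(ig_shape=0.0)
        full = m.BYMConfig.full_scale(seed=1)
        assert (full.n_iter, full.n_burnin, full.thin) == (1_500_000, 500_000, 100)


class TestSummarise:
    def test_percentiles_match_sorted_array_oracle(self, fitted_chain):
        _, _, _, chain = fitted_chain
        summary = m.summarise(chain)
        draws = np.sort(chain.alpha)
        med = np.percentile(draws, 50)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        row = summary.params.loc["alpha"]
        assert row["median"] == pytest.approx(med)
        assert row["ci_low"] == pytest.approx(lo)
        assert row["ci_high"] == pytest.approx(hi)
        assert (summary.params["ci_low"] <= summary.params["median"]).all()
        assert (summary.params["median"] <= summary.params["ci_high"]).all()

    def test_fraction_of_spatial_variation_ratio(self):
        # u draws with empirical variance 9x that of v -> fraction 0.9
        t, n = 150, 40
        base = np.linspace(-1, 1, n)
        u = np.tile(3 * base, (t, 1))
        v = np.tile(base, (t, 1))
        chain = m.BYMChain(
            ids=[f"a{i}" for i in range(n)],
            alpha=np.zeros(t), beta=np.zeros((t, 0)),
            u=u, v=v, sigma2_u=np.ones(t), sigma2_v=np.ones(t),
            design=np.zeros((n, 0)), config=m.BYMConfig(seed=0),
        )
        summary = m.summarise(chain)
        assert summary.fraction_spatial_variation == pytest.approx(0.9)

    def test_degenerate_constant_chain(self):
        t, n = 120, 5
        chain = m.BYMChain(
            ids=[f"a{i}" for i in range(n)],
            alpha=np.full(t, 0.7), beta=np.zeros((t, 0)),
            u=np.zeros((t, n)), v=np.zeros((t, n)),
            sigma2_u=np.ones(t), sigma2_v=np.ones(t),
            design=np.zeros((n, 0)), config=m.BYMConfig(seed=0),
        )
        summary = m.summarise(chain)
        row = summary.params.loc["alpha"]
        assert row["median"] == 0.7
        assert row["ci_high"] - row["ci_low"] == 0.0

    def test_empty_or_short_chain_rejected(self):
        chain = m.BYMChain(
            ids=["a"], alpha=np.zeros(5), beta=np.zeros((5, 0)),
            u=np.zeros((5, 1)), v=np.zeros((5, 1)),
            sigma2_u=np.ones(5), sigma2_v=np.ones(5),
            design=np.zeros((1, 0)), config=m.BYMConfig(seed=0),
        )
        with pytest.raises(BYMError):
            m.summarise(chain)
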