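import itertools

import numpy as np
import pytest

from carsdm import (
    IcarFit,
    LandscapeSpec,
    build_cell_response,
    build_neighbor_graph,
    deviance,
    dic,
    fit_icar_bernoulli,
    make_landscape,
    make_truth,
    posterior_summary,
    simulate_occurrences,
    spatial_effect_map,
)
from carsdm.icar import split_rhat


def make_fit(beta_draws, rho_draws=None, vrho_draws=None, dev_draws=None, names=None):
    """Assemble an IcarFit directly from draw arrays (single chain)."""
    beta = np.asarray(beta_draws, float)[None, :, :]
    n_draws = beta.shape[1]
    rho = (
        np.asarray(rho_draws, float)[None, :, :]
        if rho_draws is not None
        else np.zeros((1, n_draws, 4))
    )
    vrho = (
        np.asarray(vrho_draws, float)[None, :]
        if vrho_draws is not None
        else np.ones((1, n_draws))
    )
    dev = (
        np.asarray(dev_draws, float)[None, :]
        if dev_draws is not None
        else np.zeros((1, n_draws))
    )
    names = names or ["Intercept"] + [f"x{i}" for i in range(1, beta.shape[2])]
    return IcarFit(beta, rho, vrho, dev, names)


class TestNeighborGraph:
    def test_line_of_three(self):
        g = build_neighbor_graph(np.ones((1, 3), bool))
        assert g.n_j.tolist() == [1, 2, 1]

    def test_two_by_two_rook_degrees(self):
        g = build_neighbor_graph(np.ones((2, 2), bool))
        assert g.n_j.tolist() == [2, 2, 2, 2]

    def test_queen_adds_diagonals(self):
        g = build_neighbor_graph(np.ones((2, 2), bool), scheme="queen")
        assert g.n_j.tolist() == [3, 3, 3, 3]

    def test_masked_center_matches_brute_force_edge_count(self):
        mask = np.ones((5, 5), bool)
        mask[2, 2] = False
        g = build_neighbor_graph(mask)
        # O(n^2) oracle: enumerate all valid cell pairs at rook distance 1
        cells = [(r, c) for r in range(5) for c in range(5) if mask[r, c]]
        n_edges = sum(
            abs(r1 - r2) + abs(c1 - c2) == 1
            for (r1, c1), (r2, c2) in itertools.combinations(cells, 2)
        )
        assert int(g.n_j.sum()) == 2 * n_edges

    def test_disconnected_reports_component_sizes(self):
        mask = np.zeros((3, 3), bool)
        mask[0, 0] = mask[2, 2] = mask[2, 1] = True
        with pytest.raises(ValueError, match=r"\[2, 1\]"):
            build_neighbor_graph(mask)

    def test_keep_largest_drops_minor_component(self):
        mask = np.zeros((3, 3), bool)
        mask[0, 0] = mask[2, 2] = mask[2, 1] = True
        g = build_neighbor_graph(mask, keep_largest=True)
        assert g.n == 2


class TestDeviance:
    def test_saturated_limit_is_zero(self):
        y = np.array([0.0, 1.0, 1.0, 0.0])
        X = np.ones((4, 1))
        rho = np.where(y == 1, 60.0, -60.0)
        assert deviance(np.zeros(1), rho, y, X) == pytest.approx(0.0, abs=1e-6)

    def test_intercept_only_closed_form(self):
        # 3 successes of 10 at the MLE p = 0.3
        y = np.array([1.0] * 3 + [0.0] * 7)
        X = np.ones((10, 1))
        beta = np.array([np.log(0.3 / 0.7)])
        d = deviance(beta, np.zeros(10), y, X)
        assert d == pytest.approx(-2 * (3 * np.log(0.3) + 7 * np.log(0.7)))
        assert d == pytest.approx(12.2173, abs=5e-5)

    def test_nonnegative_on_random_parameters(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n, p = 15, 3
            X = rng.standard_normal((n, p))
            y = rng.integers(0, 2, n).astype(float)
            assert deviance(rng.standard_normal(p), rng.standard_normal(n), y, X) >= 0.0


class TestDic:
    def test_degenerate_posterior_has_zero_pd(self):
        n = 6
        y = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        X = np.ones((n, 1))
        beta = np.tile([0.2], (150, 1))
        rho = np.zeros((150, n))
        d = deviance(beta[0], rho[0], y, X)
        fit = make_fit(beta, rho, np.ones(150), np.full(150, d))
        dic_val, pd_val, dbar = dic(fit, y, X)
        assert pd_val == pytest.approx(0.0, abs=1e-10)
        assert dic_val == pytest.approx(dbar)

    def test_matches_independent_recomputation_from_draws(self):
        rng = np.random.default_rng(1)
        n, p, m = 8, 2, 120
        y = rng.integers(0, 2, n).astype(float)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        beta = rng.standard_normal((m, p)) * 0.5
        rho = rng.standard_normal((m, n)) * 0.1
        rho -= rho.mean(axis=1, keepdims=True)
        devs = np.array([deviance(beta[k], rho[k], y, X) for k in range(m)])
        fit = make_fit(beta, rho, np.ones(m), devs)
        dic_val, pd_val, dbar = dic(fit, y, X)
        # independent recomputation straight from the stored draws
        dbar_o = devs.mean()
        dhat_o = deviance(beta.mean(axis=0), rho.mean(axis=0), y, X)
        assert dbar == pytest.approx(dbar_o, abs=1e-8)
        assert dic_val == pytest.approx(2 * dbar_o - dhat_o, abs=1e-8)

    def test_requires_enough_draws(self):
        fit = make_fit(np.zeros((50, 1)))
        with pytest.raises(ValueError, match="100"):
            dic(fit, np.zeros(4), np.ones((4, 1)))

    def test_nested_models_prefer_the_generating_one(self):
        # data simulated from the 1-covariate model with a negligible spatial
        # field; the 3-covariate model should rarely win on DIC
        wins = 0
        n_rep = 20
        for rep in range(n_rep):
            stack = make_landscape(
                LandscapeSpec(8, 10, 3, autocorr_range=1.5, seed=100 + rep)
            )
            graph = build_neighbor_graph(stack)
            truth = make_truth(stack, graph, [0.0, 1.5, 0.0, 0.0], 1e-8, seed=rep)
            occ = simulate_occurrences(stack, truth, seed=1000 + rep)
            y = build_cell_response(stack, occ)
            X = stack.design_matrix()
            fit_small = fit_icar_bernoulli(
                y, X[:, :2], graph, n_iter=4000, thin=10, n_chains=1, seed=rep, vrho_max=1e-6
            )
            fit_large = fit_icar_bernoulli(
                y, X, graph, n_iter=4000, thin=10, n_chains=1, seed=rep, vrho_max=1e-6
            )
            if dic(fit_small, y, X[:, :2])[0] <= dic(fit_large, y, X)[0]:
                wins += 1
        assert wins >= 0.8 * n_rep - 1e-9


class TestPosteriorSummary:
    def test_constant_draws(self):
        fit = make_fit(np.full((200, 1), 3.25))
        s = posterior_summary(fit)
        row = s.loc["Intercept"]
        assert row["Mean"] == 3.25 and row["SD"] == 0.0
        assert row["Q0.025"] == 3.25 and row["Q0.975"] == 3.25

    def test_quantiles_match_type7_oracle(self):
        draws = np.arange(1.0, 101.0)
        fit = make_fit(draws[:, None])
        s = posterior_summary(fit, force=True)  # a ramp is not stationary

        def type7(x, q):
            x = np.sort(x)
            h = (len(x) - 1) * q
            lo = int(np.floor(h))
            return x[lo] + (h - lo) * (x[min(lo + 1, len(x) - 1)] - x[lo])

        assert s.loc["Intercept", "Q0.025"] == pytest.approx(type7(draws, 0.025))
        assert s.loc["Intercept", "Q0.975"] == pytest.approx(type7(draws, 0.975))

    def test_normal_sample_summary(self):
        rng = np.random.default_rng(7)
        draws = rng.standard_normal(100_000)
        fit = make_fit(draws[:, None])
        s = posterior_summary(fit)
        assert abs(s.loc["Intercept", "Mean"]) < 0.02
        assert abs(s.loc["Intercept", "SD"] - 1.0) < 0.02

    def test_unconverged_fit_refuses_unless_forced(self):
        # two chains stuck at different values -> huge R-hat
        beta = np.concatenate([np.zeros((1, 200, 1)), np.ones((1, 200, 1))])
        fit = IcarFit(
            beta,
            np.zeros((2, 200, 3)),
            np.ones((2, 200)),
            np.zeros((2, 200)),
            ["Intercept"],
        )
        with pytest.raises(RuntimeError, match="R-hat"):
            posterior_summary(fit)
        s = posterior_summary(fit, force=True)
        assert s.loc["Intercept", "Mean"] == pytest.approx(0.5)

    def test_split_rhat_near_one_for_iid_draws(self):
        rng = np.random.default_rng(0)
        assert split_rhat(rng.standard_normal((2, 1000))) < 1.01


@pytest.fixture(scope="module")
def sim():
    stack = make_landscape(LandscapeSpec(10, 12, 2, autocorr_range=1.5, seed=2))
    graph = build_neighbor_graph(stack)
    truth = make_truth(stack, graph, [0.0, 1.5, -1.0], 1.0, seed=3)
    occ = simulate_occurrences(stack, truth, seed=4)
    y = build_cell_response(stack, occ)
    return stack, graph, y, stack.design_matrix()


class TestFit:

    def test_same_seed_identical_draws(self, sim):
        stack, graph, y, X = sim
        kw = dict(n_iter=600, thin=5, n_chains=1, seed=11)
        f1 = fit_icar_bernoulli(y, X, graph, **kw)
        f2 = fit_icar_bernoulli(y, X, graph, **kw)
        assert np.array_equal(f1.beta, f2.beta)
        assert np.array_equal(f1.rho, f2.rho)
        assert np.array_equal(f1.vrho, f2.vrho)

    def test_rho_draws_sum_to_zero_and_vrho_positive(self, sim):
        stack, graph, y, X = sim
        fit = fit_icar_bernoulli(y, X, graph, n_iter=600, thin=5, n_chains=1, seed=1)
        assert np.all(np.abs(fit.rho_draws.sum(axis=1)) < 1e-6)
        assert np.all(fit.vrho_draws > 0)

    def test_balanced_intercept_only_centers_at_zero(self):
        graph = build_neighbor_graph(np.ones((4, 10), bool))
        y = np.tile([0.0, 1.0], 20)
        X = np.ones((40, 1))
        fit = fit_icar_bernoulli(
            y, X, graph, n_iter=4000, thin=5, n_chains=1, seed=9, vrho_max=0.01
        )
        b = fit.beta_draws[:, 0]
        assert abs(b.mean()) < 3 * b.std()

    def test_matches_logistic_mle_when_spatial_effect_suppressed(self, sim):
        import statsmodels.api as sm

        stack, graph, y, X = sim
        fit = fit_icar_bernoulli(
            y, X, graph, n_iter=6000, thin=5, n_chains=1, seed=2, vrho_max=1e-6
        )
        mle = sm.Logit(y, X).fit(disp=0)
        for j in range(X.shape[1]):
            post = fit.beta_draws[:, j]
            assert abs(post.mean() - mle.params[j]) < 2 * post.std()

    def test_all_one_response_warns(self):
        graph = build_neighbor_graph(np.ones((3, 4), bool))
        with pytest.warns(UserWarning, match="all-0 or all-1"):
            fit_icar_bernoulli(
                np.ones(12), np.ones((12, 1)), graph, n_iter=300, thin=5, n_chains=1, seed=0
            )

    def test_nonfinite_design_rejected(self):
        graph = build_neighbor_graph(np.ones((2, 2), bool))
        X = np.ones((4, 1))
        X[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_icar_bernoulli(np.zeros(4), X, graph, n_iter=100, n_chains=1, seed=0)

    def test_label_permutation_leaves_beta_unchanged_statistically(self, sim):
        stack, graph, y, X = sim
        kw = dict(n_iter=3000, thin=5, n_chains=1, seed=3)
        fit = fit_icar_bernoulli(y, X, graph, **kw)
        # consistently permute cells: reverse row-major order (an automorphism
        # of the rook grid graph)
        n = graph.n
        perm = np.arange(n)[::-1]
        inv = np.argsort(perm)
        adj_p = [np.sort(inv[graph.adjacency[perm[i]]]) for i in range(n)]
        from carsdm.landscape import NeighborGraph

        graph_p = NeighborGraph(n, adj_p, graph.rows[perm], graph.cols[perm])
        fit_p = fit_icar_bernoulli(y[perm], X[perm], graph_p, **kw)
        for j in range(X.shape[1]):
            a, b = fit.beta_draws[:, j], fit_p.beta_draws[:, j]
            se = np.sqrt(a.var() / len(a) + b.var() / len(b))
            assert abs(a.mean() - b.mean()) < 8 * se

    def test_spatial_effect_map_values_and_centering(self, sim):
        stack, graph, y, X = sim
        fit = fit_icar_bernoulli(y, X, graph, n_iter=600, thin=5, n_chains=1, seed=5)
        grid = spatial_effect_map(fit, stack)
        vals = grid.values[stack.mask]
        assert np.allclose(vals, fit.rho_draws.mean(axis=0))
        assert abs(vals.sum()) < 1e-3 * len(vals)
        # all-zero draws -> all-zero map
        zfit = make_fit(
            np.zeros((150, X.shape[1])), np.zeros((150, stack.n_valid))
        )
        zgrid = spatial_effect_map(zfit, stack)
        assert np.all(zgrid.values[stack.mask] == 0.0)

    def test_fit_roundtrips_through_disk(self, sim, tmp_path):
        stack, graph, y, X = sim
        fit = fit_icar_bernoulli(y, X, graph, n_iter=600, thin=5, n_chains=2, seed=8)
        fit.save(tmp_path / "fit")
        back = fit.load(tmp_path / "fit")
        assert np.allclose(back.beta, fit.beta)
        assert np.allclose(back.rho, fit.rho)
        assert np.allclose(back.vrho, fit.vrho)
        assert back.coef_names == fit.coef_names
        assert back.meta["n_iter"] == fit.meta["n_iter"]

    def test_misaligned_map_rejected(self, sim):
        stack, graph, y, X = sim
        fit = make_fit(np.zeros((150, 3)), np.zeros((150, 7)))
        with pytest.raises(ValueError):
            spatial_effect_map(fit, stack)
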