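"""Hierarchical model: linear predictor, reference log joint, MCMC
contracts (determinism, centering, convergence reporting) and posterior
summaries."""

import warnings

import numpy as np
import pytest
from scipy import integrate

from quantrisk import (
    ConvergenceWarning,
    MeanRiskModel,
    PanelData,
    PosteriorSamples,
    QuantileModelConfig,
    QuantileRiskModel,
    RegionGraph,
    linear_predictor,
    log_joint_quantile,
    make_lattice_graph,
)
from quantrisk.model import MeanRiskResults, QuantileRiskResults


def _panel(y, e, region_ids=None, times=None):
    y = np.asarray(y)
    n, T = y.shape
    return PanelData(
        region_ids=region_ids or [f"r{i}" for i in range(n)],
        times=times or list(range(1, T + 1)),
        y=y,
        e=np.broadcast_to(np.asarray(e, dtype=float), (n, T)).copy(),
    )


def _single_region_graph():
    return RegionGraph(region_ids=["r0"], neighbors={"r0": set()})


def _synthetic_results(cls, model, z_draws, eta_draws=None):
    """Results object with hand-made draws (all monitored keys present)."""
    chains, keep, n, T = z_draws.shape
    draws = {
        "z": z_draws,
        "eta": eta_draws if eta_draws is not None else z_draws.copy(),
        "theta": np.zeros_like(z_draws),
        "u": np.zeros((chains, keep, n)),
        "v": np.zeros((chains, keep, n)),
        "lam": np.zeros((chains, keep, T)),
    }
    for s in ("sigma_u", "sigma_v", "sigma_lam", "sigma_theta", "sigma_eps"):
        draws[s] = np.ones((chains, keep))
    samples = PosteriorSamples(
        draws=draws,
        region_ids=list(model.data.region_ids),
        times=list(model.data.times),
    )
    return cls(model, samples, QuantileModelConfig())


class TestLinearPredictor:
    def test_all_zero(self):
        eta = linear_predictor(None, None, np.zeros(2), np.zeros(2), np.zeros(3), np.zeros((2, 3)))
        np.testing.assert_array_equal(eta, 0.0)

    def test_additivity_example(self):
        eta = linear_predictor(
            None, None, np.array([1.0, 0.0]), np.zeros(2), np.array([0.0, 2.0]), np.zeros((2, 2))
        )
        np.testing.assert_allclose(eta, [[1.0, 3.0], [0.0, 2.0]])

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(0)
        n, T, p = 3, 4, 2
        u, v = rng.normal(size=n), rng.normal(size=n)
        lam, theta = rng.normal(size=T), rng.normal(size=(n, T))
        X, beta = rng.normal(size=(n, T, p)), rng.normal(size=p)
        eta = linear_predictor(beta, X, u, v, lam, theta)
        for i in range(n):
            for t in range(T):
                expect = X[i, t] @ beta + u[i] + v[i] + lam[t] + theta[i, t]
                assert eta[i, t] == pytest.approx(expect, rel=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="conform"):
            linear_predictor(None, None, np.zeros(3), np.zeros(2), np.zeros(3), np.zeros((2, 3)))


class TestLogJoint:
    def _state(self, n, T, rng=None):
        rng = rng or np.random.default_rng(0)
        return {
            "z": rng.normal(size=(n, T)) * 0.3,
            "u": rng.normal(size=n) * 0.3,
            "v": rng.normal(size=n) * 0.3,
            "lam": rng.normal(size=T) * 0.3,
            "theta": rng.normal(size=(n, T)) * 0.3,
            "sigma_u": 0.8,
            "sigma_v": 0.5,
            "sigma_lam": 0.6,
            "sigma_theta": 0.4,
            "sigma_eps": 0.7,
        }

    def test_single_unit_poisson_term(self):
        """y=0, e=1, mu=1, everything else zeroed: the Poisson contribution
        is log P(0 | 1) = -1."""
        data = _panel([[0]], 1.0)
        graph = _single_region_graph()
        cfg = QuantileModelConfig(tau=0.5)
        state = self._state(1, 1)
        for k in ("z", "u", "v", "lam", "theta"):
            state[k] = np.zeros_like(np.asarray(state[k]))
        base = log_joint_quantile(state, data, graph, cfg)
        # subtract the prior pieces by comparing against a state with the
        # same priors but y chosen so the Poisson term vanishes is awkward;
        # instead check the analytic total directly
        tau = 0.5
        expect = -1.0  # Poisson
        expect += np.log(tau * (1 - tau) / state["sigma_eps"])  # AL at r=0
        for s, k in (("sigma_v", 1), ("sigma_lam", 1), ("sigma_theta", 1)):
            expect += -0.5 * np.log(2 * np.pi) - np.log(state[s])
        assert base == pytest.approx(expect, rel=1e-12)

    def test_icar_level_shift_moves_only_v_prior(self):
        """Shifting u by a constant and v by its negative leaves the
        likelihood and the pairwise ICAR term untouched; the total changes
        exactly by the Gaussian v-prior difference."""
        graph = make_lattice_graph(2, 2)
        data = _panel(np.arange(8).reshape(4, 2), 5.0)
        cfg = QuantileModelConfig(tau=0.3)
        state = self._state(4, 2)
        base = log_joint_quantile(state, data, graph, cfg)
        c = 0.37
        shifted = dict(state)
        shifted["u"] = state["u"] + c
        shifted["v"] = state["v"] - c
        got = log_joint_quantile(shifted, data, graph, cfg)
        s_v = state["sigma_v"]
        dv = np.sum((state["v"] - c) ** 2 - state["v"] ** 2) / (2 * s_v**2)
        assert got - base == pytest.approx(-dv, rel=1e-9)

    def test_out_of_support_returns_neg_inf(self):
        graph = make_lattice_graph(2, 2)
        data = _panel(np.ones((4, 2)), 1.0)
        cfg = QuantileModelConfig()
        state = self._state(4, 2)
        for key, bad in [("sigma_u", -1.0), ("sigma_eps", 0.0), ("sigma_v", 11.0)]:
            s = dict(state)
            s[key] = bad
            assert log_joint_quantile(s, data, graph, cfg) == -np.inf


class TestFitContracts:
    def _tiny_fit(self, cls, seed=3, **kw):
        graph = make_lattice_graph(2, 2)
        rng = np.random.default_rng(0)
        y = rng.poisson(50, size=(4, 3))
        data = _panel(y, 50.0, region_ids=list(graph.region_ids))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            return cls(data, graph).fit(
                chains=2, iterations=400, burn_in=200, seed=seed, **kw
            )

    @pytest.mark.parametrize("cls", [QuantileRiskModel, MeanRiskModel])
    def test_bitwise_deterministic(self, cls):
        r1 = self._tiny_fit(cls, seed=7)
        r2 = self._tiny_fit(cls, seed=7)
        for k in r1.samples.draws:
            np.testing.assert_array_equal(r1.samples.get(k), r2.samples.get(k))

    def test_different_seeds_differ(self):
        r1 = self._tiny_fit(QuantileRiskModel, seed=1)
        r2 = self._tiny_fit(QuantileRiskModel, seed=2)
        assert not np.array_equal(r1.samples.get("z"), r2.samples.get("z"))

    def test_retained_draw_count_and_thinning(self):
        res = self._tiny_fit(QuantileRiskModel, thin=2)
        assert res.samples.n_chains == 2
        assert res.samples.n_draws == (400 - 200) // 2

    def test_u_centered_every_draw(self):
        res = self._tiny_fit(QuantileRiskModel)
        u = res.samples.get("u")
        np.testing.assert_allclose(u.sum(axis=-1), 0.0, atol=1e-10)

    def test_disconnected_graph_rejected(self):
        g = RegionGraph(
            region_ids=["a", "b"], neighbors={"a": set(), "b": set()}
        )
        data = _panel(np.ones((2, 2)), 1.0, region_ids=["a", "b"])
        with pytest.raises(ValueError, match="connected"):
            QuantileRiskModel(data, g)

    def test_region_mismatch_rejected(self):
        g = make_lattice_graph(2, 1)
        data = _panel(np.ones((2, 2)), 1.0, region_ids=["x", "y"])
        with pytest.raises(ValueError, match="match"):
            QuantileRiskModel(data, g)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="tau"):
            QuantileModelConfig(tau=1.5)
        with pytest.raises(ValueError, match="iterations"):
            QuantileModelConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError, match="chains"):
            QuantileModelConfig(chains=1)


class TestSingleUnitPosterior:
    """Large-count single-cell checks against a one-dimensional numeric
    posterior (Poisson likelihood with a flat prior on log mu)."""

    def _oracle_mean(self, y, e):
        grid = np.linspace(np.log(y / e) - 0.5, np.log(y / e) + 0.5, 4001)
        logpost = y * grid - e * np.exp(grid)
        w = np.exp(logpost - logpost.max())
        return integrate.trapezoid(np.exp(grid) * w, grid) / integrate.trapezoid(w, grid)

    @pytest.mark.parametrize("cls", [QuantileRiskModel, MeanRiskModel])
    def test_posterior_mu_concentrates(self, cls):
        data = _panel([[900]], 100.0)
        graph = _single_region_graph()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            res = cls(data, graph).fit(chains=2, iterations=4000, burn_in=2000, seed=5)
        post_mean = float(res.mu_draws.mean())
        oracle = self._oracle_mean(900, 100.0)
        assert oracle == pytest.approx(9.0, abs=0.1)
        # the hierarchy adds mild extra spread around the data-dominated mode
        assert post_mean == pytest.approx(oracle, abs=0.5)


class TestSummaries:
    def _model(self):
        graph = make_lattice_graph(2, 1)
        data = _panel(np.ones((2, 2)), 1.0, region_ids=list(graph.region_ids))
        return MeanRiskModel(data, graph)

    def test_quantile_surface_constant_eta(self):
        model = self._model()
        z = np.zeros((2, 3, 2, 2))
        qres = _synthetic_results(
            QuantileRiskResults, model, z, eta_draws=np.full_like(z, np.log(2.0))
        )
        np.testing.assert_allclose(qres.quantile_surface(), 2.0)
        zres = _synthetic_results(QuantileRiskResults, model, z)
        np.testing.assert_allclose(zres.quantile_surface(), 1.0)

    def test_mean_model_quantiles_type7(self):
        model = self._model()
        vals = np.log(np.array([1.0, 2.0, 3.0, 4.0]))
        z = np.tile(vals[None, :, None, None], (1, 1, 2, 2)).reshape(1, 4, 2, 2)
        z = np.concatenate([z, z], axis=0)  # 2 identical chains
        res = _synthetic_results(MeanRiskResults, model, z)
        np.testing.assert_allclose(res.quantile_surface(0.5), 2.5)
        # degenerate draws return the common value at any level
        zc = np.full((2, 4, 2, 2), np.log(3.0))
        res2 = _synthetic_results(MeanRiskResults, model, zc)
        for tau in (0.1, 0.5, 0.9):
            np.testing.assert_allclose(res2.quantile_surface(tau), 3.0)

    def test_mean_model_quantiles_match_sort_oracle(self):
        model = self._model()
        rng = np.random.default_rng(6)
        z = rng.normal(size=(2, 50, 2, 2))
        res = _synthetic_results(MeanRiskResults, model, z)
        tau = 0.7
        got = res.quantile_surface(tau)
        mu = np.exp(z.reshape(100, 2, 2))
        for i in range(2):
            for t in range(2):
                s = np.sort(mu[:, i, t])
                h = (len(s) - 1) * tau
                lo, hi = int(np.floor(h)), int(np.ceil(h))
                expect = s[lo] + (h - lo) * (s[hi] - s[lo])
                assert got[i, t] == pytest.approx(expect, rel=1e-12)

    def test_convergence_warning_on_separated_chains(self):
        model = self._model()
        z = np.zeros((2, 50, 2, 2))
        z[1] += 5.0
        z += np.random.default_rng(0).normal(size=z.shape) * 0.01
        with pytest.warns(ConvergenceWarning, match="R-hat"):
            _synthetic_results(MeanRiskResults, model, z)

    def test_summary_table_and_export(self, tmp_path):
        res = TestFitContracts()._tiny_fit(QuantileRiskModel)
        table = res.summary()
        assert {"mean", "sd", "median", "q2.5", "q97.5", "rhat"} <= set(table.columns)
        assert "sigma_u" in table.index
        out = tmp_path / "draws.csv"
        res.to_csv(out, params=["sigma_u", "lam"])
        import pandas as pd

        df = pd.read_csv(out)
        assert {"chain", "draw", "sigma_u"} <= set(df.columns)
        assert len(df) == res.samples.n_chains * res.samples.n_draws
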