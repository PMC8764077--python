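import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bivintent import (
    MCMCConfig,
    generate_bbg_data,
    rhogit,
    rhogit_inverse,
)
from bivintent.bbg import (
    BBGDraws,
    RankError,
    _Evaluator,
    dic,
    fit_ml,
    forward_select,
    run_mcmc,
    spline_effect,
    summarize,
)
from bivintent.design import DesignSpec, build_design


def _fit_simple(n=2000, seed=0, effect=20.0):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n).astype(float)
    X = np.column_stack([np.ones(n), x])
    df = generate_bbg_data(
        (50.0, effect), (30.0, -10.0), (np.log(10), 0.3), (np.log(8), -0.2),
        (rhogit(0.4), 0.5), X=X, seed=seed + 1,
    )
    data = pd.DataFrame({"y1": df.y1, "y2": df.y2, "x": x})
    designs = build_design(DesignSpec.shared(["x"]), data)
    y = data[["y1", "y2"]].to_numpy()
    return data, designs, y


class TestRhogit:
    def test_closed_form_values(self):
        assert rhogit(0.0) == 0.0
        assert rhogit(0.6) == pytest.approx(0.75, abs=1e-12)

    @pytest.mark.parametrize("rho", [-0.99, -0.5, 0.0, 0.5, 0.99])
    def test_round_trip(self, rho):
        assert rhogit_inverse(rhogit(rho)) == pytest.approx(rho, abs=1e-12)

    def test_strictly_increasing_and_odd(self):
        grid = np.linspace(-0.999, 0.999, 201)
        vals = rhogit(grid)
        assert np.all(np.diff(vals) > 0)
        assert np.allclose(vals, -rhogit(-grid))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            rhogit(1.0)


class TestLoglik:
    def test_standard_normal_point_density(self):
        data = pd.DataFrame({"y1": [0.0], "y2": [0.0]})
        designs = build_design(DesignSpec.shared([]), data)
        ev = _Evaluator(data.to_numpy(), designs)
        vec = np.zeros(5)
        assert ev.loglik(vec) == pytest.approx(-np.log(2 * np.pi), abs=1e-12)

    def test_zero_correlation_factorizes(self, rng):
        n = 50
        data = pd.DataFrame({"y1": rng.normal(2, 3, n), "y2": rng.normal(-1, 2, n)})
        designs = build_design(DesignSpec.shared([]), data)
        ev = _Evaluator(data.to_numpy(), designs)
        vec = np.array([2.0, -1.0, np.log(3.0), np.log(2.0), 0.0])
        marg1 = stats.norm.logpdf(data.y1, 2.0, 3.0).sum()
        marg2 = stats.norm.logpdf(data.y2, -1.0, 2.0).sum()
        assert ev.loglik(vec) == pytest.approx(marg1 + marg2, abs=1e-9)

    def test_matches_marginal_conditional_decomposition(self, rng):
        """Oracle: N2 density as marginal(y1) x conditional(y2 | y1)."""
        n = 100
        data = pd.DataFrame({"y1": rng.normal(size=n), "y2": rng.normal(size=n)})
        designs = build_design(DesignSpec.shared([]), data)
        ev = _Evaluator(data.to_numpy(), designs)
        for _ in range(10):
            mu1, mu2 = rng.normal(size=2)
            s1, s2 = np.exp(rng.normal(size=2) * 0.5)
            rho = rng.uniform(-0.95, 0.95)
            vec = np.array([mu1, mu2, np.log(s1), np.log(s2), rhogit(rho)])
            pointwise = ev.pointwise(ev.etas(ev.unpack(vec)))
            cond_mean = mu2 + rho * s2 / s1 * (data.y1 - mu1)
            cond_sd = s2 * np.sqrt(1 - rho**2)
            oracle = stats.norm.logpdf(data.y1, mu1, s1) + stats.norm.logpdf(
                data.y2, cond_mean, cond_sd
            )
            assert np.allclose(pointwise, oracle, atol=1e-10)

    def test_gradient_matches_finite_differences(self, rng):
        data, designs, y = _fit_simple(n=60, seed=3)
        ev = _Evaluator(y, designs)
        vec = np.array([48, 5, 28, -2, 2.0, 0.1, 2.0, -0.1, 0.3, 0.2], float)
        from scipy.optimize import approx_fprime

        num = approx_fprime(vec, ev.loglik, 1e-6)
        assert np.allclose(ev.grad(vec), num, rtol=1e-4, atol=1e-4)

    def test_positive_definite_sigma_for_random_parameters(self, rng):
        """Link safety: any finite coefficients give a valid covariance."""
        data, designs, y = _fit_simple(n=30, seed=4)
        ev = _Evaluator(y, designs)
        for _ in range(50):
            vec = rng.normal(scale=3.0, size=10)
            params = ev.unpack(vec)
            etas = ev.etas(params)
            s1 = np.exp(np.clip(etas["logsigma1"], -40, 40))
            s2 = np.exp(np.clip(etas["logsigma2"], -40, 40))
            rho = rhogit_inverse(etas["rhogit"])
            for i in range(len(s1)):
                sig = np.array(
                    [
                        [s1[i] ** 2, rho[i] * s1[i] * s2[i]],
                        [rho[i] * s1[i] * s2[i], s2[i] ** 2],
                    ]
                )
                np.linalg.cholesky(sig)  # raises if not PD


class TestFitML:
    def test_binary_effect_recovery(self):
        data, designs, y = _fit_simple(n=5000, seed=5)
        fit = fit_ml(designs, y)
        truth = np.array([50, 20, 30, -10, np.log(10), 0.3, np.log(8), -0.2,
                          rhogit(0.4), 0.5])
        z = (fit.vector() - truth) / fit.standard_errors()
        assert np.all(np.abs(z) < 3)
        assert abs(fit.params["mu1"][1] - 20) < 1.0

    def test_refit_from_solution_is_fixed_point(self):
        data, designs, y = _fit_simple(n=500, seed=6)
        fit = fit_ml(designs, y)
        refit = fit_ml(designs, y, init=fit.vector())
        assert np.allclose(fit.vector(), refit.vector(), atol=1e-8)

    def test_reduces_to_ols_with_frozen_correlation(self):
        data, designs, y = _fit_simple(n=800, seed=7)
        fit = fit_ml(designs, y, fixed={"rhogit": np.zeros(2)})
        X = designs.X["mu1"]
        for j, block in enumerate(["mu1", "mu2"]):
            ols = np.linalg.lstsq(X, y[:, j], rcond=None)[0]
            assert np.allclose(fit.params[block], ols, atol=1e-6)

    def test_zero_coefficient_on_extra_column_leaves_loglik_unchanged(self):
        data, designs, y = _fit_simple(n=200, seed=8)
        ev = _Evaluator(y, designs)
        vec = np.array([50, 5, 30, -2, 2.3, 0.1, 2.0, -0.1, 0.4, 0.2], float)
        base = ev.loglik(vec)
        data2 = data.assign(z=0.0)
        designs2 = build_design(DesignSpec.shared(["x", "z"]), data2)
        ev2 = _Evaluator(y, designs2)
        vec2 = np.insert(vec, [2, 4, 6, 8, 10], 0.0)
        assert ev2.loglik(vec2) == pytest.approx(base, abs=1e-10)

    def test_duplicated_column_raises_rank_error(self):
        data, designs, y = _fit_simple(n=100, seed=9)
        data2 = data.assign(x2=data["x"])
        designs2 = build_design(DesignSpec.shared(["x", "x2"]), data2)
        with pytest.raises(RankError, match="x2"):
            fit_ml(designs2, y)


class TestMCMC:
    def test_same_seed_gives_identical_chains(self):
        data, designs, y = _fit_simple(n=300, seed=10)
        fit = fit_ml(designs, y)
        cfg = MCMCConfig(iterations=400, burnin=100, seed=42)
        d1 = run_mcmc(fit, cfg)
        d2 = run_mcmc(fit, cfg)
        assert np.array_equal(d1.draws, d2.draws)
        d3 = run_mcmc(fit, MCMCConfig(iterations=400, burnin=100, seed=43))
        assert not np.array_equal(d1.draws, d3.draws)

    def test_posterior_means_agree_with_ml_on_strong_signal(self):
        data, designs, y = _fit_simple(n=5000, seed=11)
        fit = fit_ml(designs, y)
        draws = run_mcmc(fit, MCMCConfig(iterations=2500, burnin=500, seed=1))
        post_mean = draws.draws.mean(axis=0)
        post_sd = draws.draws.std(axis=0)
        assert np.all(np.abs(post_mean - fit.vector()) < 0.5 * post_sd + 1e-8)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(iterations=100, burnin=100)


class TestSummarizeAndDic:
    def _draws_from(self, arr, names=None):
        arr = np.asarray(arr, dtype=float)
        names = names or [f"b{i}" for i in range(arr.shape[1])]
        return BBGDraws(
            draws=arr, names=names, slices={}, acceptance={},
            config=MCMCConfig(iterations=200, burnin=0), fit=None,
        )

    def test_constant_draws_degenerate_interval(self):
        d = self._draws_from(np.full((200, 1), 3.5))
        s = summarize(d)
        row = s.table.iloc[0]
        assert row["mean"] == row["q2.5"] == row["q97.5"] == 3.5

    def test_standard_normal_interval(self, rng):
        d = self._draws_from(rng.standard_normal((100_000, 1)))
        row = summarize(d).table.iloc[0]
        assert row["q2.5"] == pytest.approx(-1.96, abs=0.02)
        assert row["q97.5"] == pytest.approx(1.96, abs=0.02)

    def test_flag_iff_interval_excludes_zero(self, rng):
        arr = np.column_stack(
            [rng.normal(5, 0.1, 500), rng.normal(0, 1, 500)]
        )
        t = summarize(self._draws_from(arr)).table
        assert bool(t.loc[0, "excl_zero"]) is True
        assert bool(t.loc[1, "excl_zero"]) is False
        for _, r in t.iterrows():
            assert r["excl_zero"] == (not (r["q2.5"] <= 0 <= r["q97.5"]))

    def test_dic_at_point_mass_equals_deviance(self):
        data, designs, y = _fit_simple(n=200, seed=12)
        fit = fit_ml(designs, y)
        arr = np.tile(fit.vector(), (200, 1))
        d = BBGDraws(
            draws=arr, names=fit.names, slices=fit.slices(), acceptance={},
            config=MCMCConfig(iterations=200, burnin=0), fit=fit,
        )
        assert dic(d) == pytest.approx(-2 * fit.loglik, abs=1e-8)


class TestSelectionAndSpline:
    def test_strong_covariate_beats_null_model(self):
        data, designs, y = _fit_simple(n=800, seed=13, effect=25.0)
        cfg = MCMCConfig(iterations=800, burnin=200, seed=3)
        spec, trace = forward_select(
            ["x"], data, responses=("y1", "y2"), config=cfg
        )
        assert "x" in spec.all_terms()
        dic_null = trace.loc[trace.step == 0, "dic"].iloc[0]
        dic_x = trace.loc[trace.candidate == "x", "dic"].iloc[0]
        assert dic_x < dic_null - 100

    def test_empty_candidate_list_returns_intercept_only(self):
        data, designs, y = _fit_simple(n=300, seed=14)
        cfg = MCMCConfig(iterations=400, burnin=100, seed=4)
        spec, trace = forward_select([], data, responses=("y1", "y2"), config=cfg)
        assert spec.all_terms() == []
        assert len(trace) == 1

    def test_zero_spline_coefficients_give_flat_curve(self):
        rng = np.random.default_rng(15)
        n = 300
        data = pd.DataFrame(
            {"y1": rng.normal(50, 5, n), "y2": rng.normal(30, 5, n),
             "age": rng.uniform(18, 80, n)}
        )
        spec = DesignSpec.shared(["s(age)"])
        designs = build_design(spec, data)
        fit = fit_ml(designs, data[["y1", "y2"]].to_numpy())
        k = fit.vector().size
        arr = np.zeros((200, k))
        d = BBGDraws(
            draws=arr, names=fit.names, slices=fit.slices(), acceptance={},
            config=MCMCConfig(iterations=200, burnin=0), fit=fit,
        )
        eff = spline_effect(d, "mu1", "age")
        assert np.allclose(eff["mean"], 0.0)
        assert np.allclose(eff["q2.5"], 0.0)
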