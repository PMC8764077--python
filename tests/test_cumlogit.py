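import numpy as np
import pandas as pd
import pytest
from scipy import special

from bivintent import (
    SurveyDataset,
    SyntheticConfig,
    generate_ordinal_data,
    generate_survey,
)
from bivintent.cumlogit import (
    fit_conspiracy,
    fit_cumlogit,
    loglik_fixed,
    loglik_mixed,
    long_to_wide,
    odds_ratios,
    reshape_long,
    _log_cell_prob,
)


@pytest.fixture(scope="module")
def toy_mixed():
    """5 subjects x 4 responses with one binary covariate."""
    rng = np.random.default_rng(21)
    X = rng.integers(0, 2, 20).reshape(20, 1).astype(float)
    tab = generate_ordinal_data((-1.0, 0.0, 1.0), (0.5,), 1.0, 5, 4, X=X, seed=22)
    return (
        np.array([-1.0, 0.0, 1.0]),
        np.array([0.5]),
        tab[["x1"]].to_numpy(),
        tab["response"].to_numpy(),
        tab["respondent_id"].to_numpy(),
    )


def _brute_force_mixed(theta, beta, sigma, X, y, subject, lo=-8, hi=8, m=4001):
    """Trapezoid integration over the random intercept, per subject."""
    u = np.linspace(lo, hi, m)
    total = 0.0
    K = theta.size + 1
    for j in np.unique(subject):
        mask = subject == j
        prod = np.ones_like(u)
        for xi, yi in zip(X[mask] @ beta, y[mask]):
            up = theta[yi - 1] - xi - u if yi < K else np.full_like(u, np.inf)
            lw = theta[yi - 2] - xi - u if yi > 1 else np.full_like(u, -np.inf)
            prod *= special.expit(up) - special.expit(lw)
        dens = np.exp(-(u**2) / (2 * sigma**2)) / np.sqrt(2 * np.pi * sigma**2)
        total += np.log(np.trapezoid(prod * dens, u))
    return total


class TestReshape:
    def test_single_subject_bookkeeping(self, tiny_wide):
        one = tiny_wide.iloc[[0]]
        long = reshape_long(one)
        assert len(long) == 4
        row = long.set_index(["measure_type", "motivation_target"])
        assert row.loc[("COVID-19 vaccine", "for myself"), "response_raw"] == 3
        assert row.loc[("CTA Immuni", "for others"), "response_raw"] == 2

    def test_four_rows_per_subject(self, survey200):
        long = reshape_long(survey200)
        assert len(long) == 4 * survey200.n
        assert (long.groupby("respondent_id").size() == 4).all()
        assert long["response"].isin([1, 2, 3, 4]).all()

    def test_round_trip_is_lossless(self, survey200):
        long = reshape_long(survey200)
        wide = long_to_wide(long)
        cols = [
            "motivation_vaccine_self", "motivation_vaccine_others",
            "motivation_cta_self", "motivation_cta_others",
        ]
        orig = survey200.table[["respondent_id"] + cols].sort_values(
            "respondent_id"
        ).reset_index(drop=True)
        back = wide[["respondent_id"] + cols].sort_values(
            "respondent_id"
        ).reset_index(drop=True)
        pd.testing.assert_frame_equal(orig, back, check_dtype=False)

    def test_duplicate_subject_rejected(self, tiny_wide):
        df = pd.concat([tiny_wide, tiny_wide.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicated"):
            reshape_long(df)


class TestMixedLikelihood:
    def test_sigma_zero_reduces_to_fixed_effects(self, toy_mixed):
        theta, beta, X, y, subj = toy_mixed
        assert loglik_mixed(theta, beta, 0.0, X, y, subj) == loglik_fixed(
            theta, beta, X, y
        )

    def test_quadrature_matches_brute_force(self, toy_mixed):
        theta, beta, X, y, subj = toy_mixed
        ll_q = loglik_mixed(theta, beta, 1.0, X, y, subj, n_nodes=25)
        ll_b = _brute_force_mixed(theta, beta, 1.0, X, y, subj)
        assert ll_q == pytest.approx(ll_b, abs=1e-6)

    def test_quadrature_converges_in_node_count(self, toy_mixed):
        theta, beta, X, y, subj = toy_mixed
        a = loglik_mixed(theta, beta, 1.3, X, y, subj, n_nodes=15)
        b = loglik_mixed(theta, beta, 1.3, X, y, subj, n_nodes=30)
        assert abs(a - b) < 1e-8

    def test_cell_probabilities_sum_to_one(self, rng):
        theta = np.array([-1.2, 0.1, 0.9])
        lin = rng.normal(size=50)
        total = np.zeros(50)
        for k in range(1, 5):
            total += np.exp(
                _log_cell_prob(theta, lin, np.full(50, k, dtype=int))
            )
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_location_shift_invariance(self, toy_mixed):
        """Shifting thresholds and the linear predictor together leaves all
        category probabilities (hence the likelihood) unchanged."""
        theta, beta, X, y, subj = toy_mixed
        shift = 2.7
        base = loglik_fixed(theta, beta, X, y)
        lin = X @ beta
        shifted = float(
            np.sum(_log_cell_prob(theta + shift, lin + shift, y))
        )
        assert shifted == pytest.approx(base, abs=1e-10)

    def test_non_monotone_thresholds_rejected(self, toy_mixed):
        theta, beta, X, y, subj = toy_mixed
        with pytest.raises(ValueError, match="increasing"):
            loglik_mixed(np.array([1.0, 0.0, -1.0]), beta, 1.0, X, y, subj)


class TestFit:
    def test_null_data_recovers_empirical_cutpoints(self):
        tab = generate_ordinal_data((-1.0, 0.2, 1.4), (), 0.0, 3000, 1, seed=30)
        fit = fit_cumlogit(tab, covariates=[], random_intercept=False)
        y = tab["response"].to_numpy()
        for k, th in enumerate(fit.thresholds, start=1):
            emp = special.logit((y <= k).mean())
            assert th == pytest.approx(emp, abs=1e-4)

    def test_mixed_recovery_within_3_se(self):
        rng = np.random.default_rng(31)
        n_subj = 300
        X = np.tile([[0.0], [1.0], [0.0], [1.0]], (n_subj, 1))
        theta = np.array([-1.0, 0.0, 1.0])
        tab = generate_ordinal_data(theta, (np.log(3),), 1.0, n_subj, 4, X=X, seed=32)
        tab["measure"] = np.where(X[:, 0] == 1, "b", "a")
        fit = fit_cumlogit(
            tab, covariates=["measure"], references={"measure": "a"}
        )
        z = (fit.beta[0] - np.log(3)) / fit.beta_se()[0]
        assert abs(z) < 3
        assert 0.5 < fit.sigma_gamma < 2.0

    def test_noise_covariate_increases_aic_usually(self):
        rng = np.random.default_rng(33)
        hits = 0
        for rep in range(20):
            tab = generate_ordinal_data(
                (-1.0, 0.0, 1.0), (), 0.8, 150, 4, seed=100 + rep
            )
            tab["noise"] = rng.normal(size=len(tab))
            base = fit_cumlogit(tab, covariates=[]).aic
            noisy = fit_cumlogit(tab, covariates=["noise"]).aic
            hits += noisy > base
        assert hits >= 13

    def test_fixed_effects_match_statsmodels(self, survey200):
        """Independent oracle for the sigma=0 path."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        long = reshape_long(survey200)
        fit = fit_cumlogit(
            long, covariates=["measure_type", "motivation_target"],
            random_intercept=False,
        )
        Xd = pd.DataFrame(
            {
                "m": (long["measure_type"] == "COVID-19 vaccine").astype(float),
                "t": (long["motivation_target"] == "for myself").astype(float),
            }
        )
        om = OrderedModel(long["response"], Xd, distr="logit").fit(
            method="bfgs", disp=False
        )
        assert fit.loglik == pytest.approx(om.llf, abs=1e-4)
        assert np.allclose(fit.beta, om.params[:2].to_numpy(), atol=1e-4)

    def test_single_level_outcome_rejected(self, survey200):
        df = survey200.table.copy()
        df["conspiracy"] = 4
        with pytest.raises(ValueError, match="single"):
            fit_cumlogit(df, outcome="conspiracy", covariates=[],
                         random_intercept=False)

    def test_proportional_odds_monotone_in_k(self):
        tab = generate_ordinal_data((-1.0, 0.0, 1.0), (0.7,), 0.0, 500, 1,
                                    X=np.random.default_rng(34).normal(
                                        size=(500, 1)), seed=35)
        fit = fit_cumlogit(tab, covariates=["x1"], random_intercept=False)
        lin = tab[["x1"]].to_numpy() @ fit.beta
        cum = special.expit(fit.thresholds[None, :] - lin[:, None])
        assert np.all(np.diff(cum, axis=1) >= 0)


class TestORTable:
    def test_reference_rows_and_flags(self):
        tab = generate_ordinal_data((-1.0, 0.0, 1.0), (0.8,), 0.0, 400, 1,
                                    X=np.random.default_rng(36).integers(
                                        0, 2, 400).reshape(-1, 1).astype(float),
                                    seed=37)
        tab["grp"] = np.where(tab["x1"] == 1, "treat", "ctrl")
        fit = fit_cumlogit(tab, covariates=["grp"], random_intercept=False,
                           references={"grp": "ctrl"})
        ors = odds_ratios(fit)
        ref = ors[ors["reference"]]
        assert (ref["OR"] == 1.0).all()
        assert ref["ci_low"].isna().all()
        assert ors["term"].str.contains(r"Intercept 1\|2").any()
        est = ors[~ors["reference"]]
        assert ((est["ci_low"] <= est["OR"]) & (est["OR"] <= est["ci_high"])).all()
        assert (est["ci_low"] > 0).all()

    def test_null_effect_interval_contains_one(self):
        tab = generate_ordinal_data((-1.0, 0.0, 1.0), (0.0,), 0.0, 600, 1,
                                    X=np.random.default_rng(38).normal(
                                        size=(600, 1)), seed=39)
        fit = fit_cumlogit(tab, covariates=["x1"], random_intercept=False)
        row = odds_ratios(fit).set_index("term").loc["x1"]
        assert row["ci_low"] <= 1.0 <= row["ci_high"]


class TestConspiracy:
    def test_seven_level_recovery(self):
        rng = np.random.default_rng(40)
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        theta = special.logit(np.array([0.1, 0.25, 0.45, 0.65, 0.82, 0.93]))
        tab = generate_ordinal_data(theta, (-0.5,), 0.0, n, 1,
                                    X=x.reshape(-1, 1), seed=41)
        df = pd.DataFrame(
            {"respondent_id": range(n), "conspiracy": tab["response"],
             "gender": np.where(x == 1, "male", "female")}
        )
        fit, ors = fit_conspiracy(df, covariates=["gender"],
                                  references={"gender": "female"})
        assert fit.n_levels == 7
        assert len(fit.thresholds) == 6
        z = (fit.beta[0] + 0.5) / fit.beta_se()[0]
        assert abs(z) < 3
        assert not fit.random_intercept
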