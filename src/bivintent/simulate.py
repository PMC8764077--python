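"""Synthetic survey generator matching the structures the models assume.

``generate_survey`` emulates the study population: n = 448 respondents,
70.8% female, age 33.8 +/- 13.9 years, a zero-inflated 0-100 vaccine-doubts
score (point mass at zero of about 0.22, the "no doubts" share, plus a
scaled Beta remainder), 3-item risk and trust blocks driven by one latent
factor each, two intention scores drawn from the bivariate Gaussian law
with covariate-dependent location/scale/correlation and clamped to [0, 100]
(producing the boundary spikes real intention scores show), and ordinal
motivation items drawn from the mixed cumulative-logistic law with a
positive dependence on perceived risk.

``generate_bbg_data`` and ``generate_ordinal_data`` draw from the bare model
laws (no clamping, no survey dressing) for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .bbg import rhogit, rhogit_inverse
from .dataset import SurveyDataset, validate


class EmptyDatasetError(ValueError):
    pass


@dataclasses.dataclass
class SyntheticConfig:
    """Study-condition defaults for the survey generator.

    The demographic margins (sample size, female share, age distribution,
    zero-doubts share, education/job/family/salary mixes) mirror the study
    sample; the true model coefficients are fixed at values producing
    intention and motivation distributions of the same shape and location
    as the observed ones.
    """

    n: int = 448
    female_prop: float = 0.708
    age_mean: float = 33.8
    age_sd: float = 13.9
    doubts_zero_prob: float = 0.219      # "no doubts" share, 98/448
    doubts_beta: tuple[float, float] = (1.2, 2.2)
    flu_prop: float = 0.112
    covid_contact_prop: float = 0.55

    # loadings on the standardized item scale (likelihood, severity, scare)
    risk_loadings: tuple[float, float, float] = (0.55, 0.80, 0.85)
    # (international, national, scientific)
    trust_loadings: tuple[float, float, float] = (0.80, 0.82, 0.90)

    # true bivariate coefficients over [1, doubts/100, risk_f, trust_f, flu]
    beta1: tuple[float, ...] = (75.0, -45.0, 5.0, 2.0, 6.0)    # vaccine mean
    beta2: tuple[float, ...] = (50.0, -15.0, 8.0, 10.0, 5.0)   # CTA mean
    gamma1: tuple[float, ...] = (3.22, 0.3, 0.0, 0.0, 0.0)     # log sigma_1
    gamma2: tuple[float, ...] = (3.40, 0.0, 0.0, 0.0, 0.0)     # log sigma_2
    beta3: tuple[float, ...] = (0.50, 0.0, -0.20, 0.0, 0.0)    # rhogit(rho)

    # true ordinal parameters over [measure=vaccine, target=self, risk_f]
    theta: tuple[float, float, float] = (-2.0, -0.5, 1.0)
    ord_beta: tuple[float, float, float] = (1.10, -0.35, 0.60)
    sigma_gamma: float = 1.2

    # conspiracy (7 levels) over [doubts/100, male]
    consp_beta: tuple[float, float] = (2.0, -0.5)

    clamp: bool = True
    seed: int = 0

    def __post_init__(self):
        for p in (self.female_prop, self.doubts_zero_prob, self.flu_prop):
            if not 0.0 <= p <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")
        if self.n < 1:
            raise EmptyDatasetError("n must be >= 1")
        if len(self.risk_loadings) != 3 or len(self.trust_loadings) != 3:
            raise ValueError("loading vectors must have length 3")


def _factor_block(
    rng: np.random.Generator, n: int, loadings: Sequence[float],
    center: float = 55.0, scale: float = 22.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One-factor 3-item block rescaled to 0-100; returns (items, factor)."""
    lam = np.asarray(loadings, dtype=float)
    f = rng.standard_normal(n)
    eps = rng.standard_normal((n, 3)) * np.sqrt(1.0 - lam**2)
    z = f[:, None] * lam + eps
    items = np.clip(center + scale * z, 0.0, 100.0)
    return items, f


def _draw_ordinal(
    rng: np.random.Generator, theta: np.ndarray, lin: np.ndarray
) -> np.ndarray:
    """Draw from the cumulative-logistic law P(Y<=k) = expit(theta_k - lin)."""
    cum = special.expit(theta[None, :] - lin[:, None])  # (n, K-1)
    u = rng.uniform(size=lin.shape[0])
    return 1 + (u[:, None] > cum).sum(axis=1)


def generate_bbg_data(
    beta1, beta2, gamma1, gamma2, beta3,
    X: np.ndarray | Mapping[str, np.ndarray] | None = None,
    n: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Independent draws from the bivariate Gaussian distributional law.

    ``X`` is either one design matrix shared by all five parameter blocks or
    a mapping with keys mu1/mu2/logsigma1/logsigma2/rhogit; ``None`` means
    intercept-only (then ``n`` is required).  No clamping is applied.
    """
    blocks = {"mu1": beta1, "mu2": beta2, "logsigma1": gamma1,
              "logsigma2": gamma2, "rhogit": beta3}
    blocks = {k: np.atleast_1d(np.asarray(v, float)) for k, v in blocks.items()}
    if X is None:
        if n is None:
            raise ValueError("n is required for intercept-only generation")
        Xd = {k: np.ones((n, 1)) for k in blocks}
    elif isinstance(X, Mapping):
        Xd = {k: np.asarray(v, float) for k, v in X.items()}
    else:
        X = np.asarray(X, float)
        Xd = {k: X for k in blocks}
    n_obs = next(iter(Xd.values())).shape[0]
    for k, coef in blocks.items():
        if Xd[k].shape[1] != coef.size:
            raise ValueError(
                f"block {k!r}: design has {Xd[k].shape[1]} columns but "
                f"{coef.size} coefficients"
            )

    rng = np.random.default_rng(seed)
    mu1 = Xd["mu1"] @ blocks["mu1"]
    mu2 = Xd["mu2"] @ blocks["mu2"]
    s1 = np.exp(Xd["logsigma1"] @ blocks["logsigma1"])
    s2 = np.exp(Xd["logsigma2"] @ blocks["logsigma2"])
    rho = rhogit_inverse(Xd["rhogit"] @ blocks["rhogit"])

    z1 = rng.standard_normal(n_obs)
    z2 = rng.standard_normal(n_obs)
    y1 = mu1 + s1 * z1
    y2 = mu2 + s2 * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)
    return pd.DataFrame({"y1": y1, "y2": y2})


def generate_ordinal_data(
    theta: Sequence[float],
    beta: Sequence[float],
    sigma_gamma: float,
    n_subjects: int,
    responses_per_subject: int = 4,
    X: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draws from the mixed cumulative-logistic law, one shared intercept
    per subject.  ``X`` has one row per response (defaults to no covariates)."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.diff(theta) > 0):
        raise ValueError("thresholds must be strictly increasing")
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    n_rows = n_subjects * responses_per_subject
    if X is None:
        lin_fixed = np.zeros(n_rows)
    else:
        X = np.asarray(X, dtype=float)
        if X.shape != (n_rows, beta.size):
            raise ValueError(f"X must be ({n_rows}, {beta.size})")
        lin_fixed = X @ beta
    rng = np.random.default_rng(seed)
    gamma = rng.normal(0.0, sigma_gamma, size=n_subjects)
    subject = np.repeat(np.arange(n_subjects), responses_per_subject)
    resp = _draw_ordinal(rng, theta, lin_fixed + gamma[subject])
    out = pd.DataFrame({"respondent_id": subject, "response": resp})
    if X is not None:
        for j in range(X.shape[1]):
            out[f"x{j+1}"] = X[:, j]
    return out


def generate_survey(config: SyntheticConfig | None = None) -> SurveyDataset:
    """Full synthetic survey; deterministic for a fixed seed and always
    passing dataset validation."""
    cfg = config or SyntheticConfig()
    root = np.random.SeedSequence(cfg.seed)
    r_demo, r_risk, r_trust, r_doubt, r_int, r_mot, r_consp, r_misc = (
        np.random.default_rng(s) for s in root.spawn(8)
    )
    n = cfg.n

    gender = np.where(r_demo.uniform(size=n) < cfg.female_prop, "female", "male")
    age = np.clip(r_demo.normal(cfg.age_mean, cfg.age_sd, size=n), 18, 90).round()
    education = r_demo.choice(
        ["middle school", "high school", "university degree or higher"],
        size=n, p=[0.074, 0.44, 0.486],
    )
    family = r_demo.choice(
        ["single", "married-living together", "other"], size=n, p=[0.49, 0.42, 0.09]
    )
    job = r_demo.choice(
        ["employee", "business-owner", "retired-unemployed", "student"],
        size=n, p=[0.415, 0.118, 0.078, 0.389],
    )
    salary = r_demo.choice(
        ["<15k", "15-55k", ">55k", "unknown"], size=n, p=[0.27, 0.45, 0.10, 0.18]
    )
    flu = (r_demo.uniform(size=n) < cfg.flu_prop).astype(int)
    contact = (r_demo.uniform(size=n) < cfg.covid_contact_prop).astype(int)

    risk_items, f_risk = _factor_block(r_risk, n, cfg.risk_loadings)
    trust_items, f_trust = _factor_block(r_trust, n, cfg.trust_loadings)

    zero = r_doubt.uniform(size=n) < cfg.doubts_zero_prob
    a, b = cfg.doubts_beta
    doubts = np.where(zero, 0.0, np.round(100.0 * r_doubt.beta(a, b, size=n), 0))
    doubts[~zero] = np.clip(doubts[~zero], 1.0, 100.0)  # keep remainder on (0,100]

    Xb = np.column_stack(
        [np.ones(n), doubts / 100.0, f_risk, f_trust, flu.astype(float)]
    )
    intents = generate_bbg_data(
        cfg.beta1, cfg.beta2, cfg.gamma1, cfg.gamma2, cfg.beta3,
        X=Xb, seed=r_int.integers(2**31),
    )
    vaccine = intents["y1"].to_numpy()
    cta = intents["y2"].to_numpy()
    if cfg.clamp:
        vaccine = np.clip(np.round(vaccine), 0, 100)
        cta = np.clip(np.round(cta), 0, 100)

    # motivation items: 4 responses per subject from the mixed ordinal law
    theta = np.asarray(cfg.theta, float)
    ob = np.asarray(cfg.ord_beta, float)
    gamma_subj = r_mot.normal(0.0, cfg.sigma_gamma, size=n)
    items = {}
    for item, (is_vax, is_self) in {
        "motivation_cta_others": (0.0, 0.0),
        "motivation_cta_self": (0.0, 1.0),
        "motivation_vaccine_others": (1.0, 0.0),
        "motivation_vaccine_self": (1.0, 1.0),
    }.items():
        lin = ob[0] * is_vax + ob[1] * is_self + ob[2] * f_risk + gamma_subj
        resp = _draw_ordinal(r_mot, theta, lin)  # 1..4 on the modelling scale
        # report on the collected 0-4 scale: the bottom modelling level maps
        # to raw 0 or 1 with equal chance
        raw = np.where(resp == 1, r_mot.integers(0, 2, size=n), resp)
        items[item] = raw

    consp_theta = special.logit(np.array([0.10, 0.25, 0.45, 0.65, 0.82, 0.93]))
    consp_lin = cfg.consp_beta[0] * (doubts / 100.0) + cfg.consp_beta[1] * (
        gender == "male"
    )
    conspiracy = _draw_ordinal(r_consp, consp_theta, consp_lin)

    trust_local = np.clip(
        60 + 15 * f_trust + r_misc.normal(0, 18, size=n), 0, 100
    ).round()
    self_eff = np.clip(
        70 + 10 * f_risk + 8 * f_trust + r_misc.normal(0, 16, size=n), 0, 100
    ).round()

    ids = [f"R{i+1:05d}" for i in range(n)]
    df = pd.DataFrame(
        {
            "respondent_id": ids,
            "vaccine_intent": vaccine,
            "cta_intent": cta,
            "motivation_vaccine_self": items["motivation_vaccine_self"],
            "motivation_vaccine_others": items["motivation_vaccine_others"],
            "motivation_cta_self": items["motivation_cta_self"],
            "motivation_cta_others": items["motivation_cta_others"],
            "risk_likelihood": risk_items[:, 0].round(),
            "risk_severity": risk_items[:, 1].round(),
            "risk_scare": risk_items[:, 2].round(),
            "trust_international": trust_items[:, 0].round(),
            "trust_national": trust_items[:, 1].round(),
            "trust_scientific": trust_items[:, 2].round(),
            "trust_local": trust_local,
            "self_efficacy": self_eff,
            "vaccine_doubts": doubts,
            "flu_vaccine_2019": flu,
            "conspiracy": conspiracy,
            "gender": gender,
            "age": age,
            "education": education,
            "family_status": family,
            "job": job,
            "salary": salary,
            "covid_contact": contact,
        }
    )
    if not cfg.clamp:
        # latent-scale intentions can leave [0, 100]; skip range validation
        # (law-checking mode only)
        return SurveyDataset(table=df)
    ds = validate(df)
    assert ds.n == n
    return ds
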