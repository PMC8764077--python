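"""Proportional-odds (cumulative logistic) models for the motivation items.

Each respondent rates four motivations (2 preventive measures x protecting
self/others) on an ordinal 1-4 scale; the wide table is reshaped to long
format (4 rows per subject) and fitted with

    logit P(Y_ij <= k) = theta_k - (x_ij' beta + gamma_j),

where gamma_j ~ N(0, sigma_gamma^2) is a subject random intercept integrated
out by adaptive Gauss-Hermite quadrature.  With sigma_gamma = 0 the model
reduces exactly to the ordinary proportional-odds regression, which is also
used (on respondent-level rows, 7 outcome levels) for the conspiracy-belief
model.  Effects are reported as odds ratios exp(beta) with Wald 95% CIs; by
the theta_k - x'beta sign convention a positive coefficient means higher
response categories are more likely.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .dataset import (
    DEFAULT_MOTIVATION_RECODE,
    MOTIVATION_ITEMS,
    SurveyDataset,
    recode_motivation,
)

MEASURE_LEVELS = ["CTA Immuni", "COVID-19 vaccine"]
TARGET_LEVELS = ["for others", "for myself"]

_ITEM_MAP = {
    "motivation_cta_others": ("CTA Immuni", "for others"),
    "motivation_cta_self": ("CTA Immuni", "for myself"),
    "motivation_vaccine_others": ("COVID-19 vaccine", "for others"),
    "motivation_vaccine_self": ("COVID-19 vaccine", "for myself"),
}


class SeparationWarning(UserWarning):
    pass


def reshape_long(
    data: SurveyDataset | pd.DataFrame,
    recode: Mapping[int, int] = DEFAULT_MOTIVATION_RECODE,
) -> pd.DataFrame:
    """Reshape the four wide motivation items into 4 rows per subject.

    Output columns: ``respondent_id``, ``measure_type`` (reference "CTA
    Immuni"), ``motivation_target`` (reference "for others"), ``response``
    (recoded 1-4), ``response_raw`` (as collected, 0-4), plus every
    subject-level covariate carried onto each row.  Wide -> long -> wide is
    lossless through ``response_raw``.
    """
    df = data.table if isinstance(data, SurveyDataset) else data
    if df["respondent_id"].duplicated().any():
        raise ValueError("duplicated respondent_id in wide table")
    carried = [c for c in df.columns if c not in MOTIVATION_ITEMS]
    rows = []
    for item, (measure, target) in _ITEM_MAP.items():
        block = df[carried].copy()
        block["measure_type"] = measure
        block["motivation_target"] = target
        block["response_raw"] = df[item].to_numpy(dtype=int)
        block["response"] = recode_motivation(df[item], recode)
        rows.append(block)
    long = pd.concat(rows, ignore_index=True)
    long["measure_type"] = pd.Categorical(
        long["measure_type"], categories=MEASURE_LEVELS
    )
    long["motivation_target"] = pd.Categorical(
        long["motivation_target"], categories=TARGET_LEVELS
    )
    return long.sort_values("respondent_id", kind="stable").reset_index(drop=True)


def long_to_wide(long: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`reshape_long` (through the raw responses)."""
    inv = {v: k for k, v in _ITEM_MAP.items()}
    wide = long.pivot_table(
        index="respondent_id",
        columns=["measure_type", "motivation_target"],
        values="response_raw",
        aggfunc="first",
        observed=True,
    )
    wide.columns = [inv[(m, t)] for m, t in wide.columns]
    return wide.reset_index()


# ---------------------------------------------------------------------------
# likelihood


def _build_X(
    df: pd.DataFrame,
    covariates: Sequence[str],
    references: Mapping[str, str] | None = None,
) -> tuple[np.ndarray, list[str], list[dict]]:
    """Intercept-free design with treatment coding; returns term metadata
    (term, level, is_reference, column index) for OR-table rendering."""
    references = dict(references or {})
    cols, names, terms = [], [], []
    for term in covariates:
        col = df[term]
        if isinstance(col.dtype, pd.CategoricalDtype):
            levels = list(col.cat.categories)
        elif pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(term)
            terms.append(
                {"term": term, "level": None, "reference": False, "col": len(cols) - 1}
            )
            continue
        else:
            observed = list(pd.unique(col.astype(str)))
            ref = references.get(term, observed[0])
            levels = [ref] + [l for l in observed if l != ref]
        vals = col.astype(str)
        terms.append(
            {"term": term, "level": levels[0], "reference": True, "col": None}
        )
        for level in levels[1:]:
            cols.append((vals == level).to_numpy(dtype=float))
            names.append(f"{term}[{level}]")
            terms.append(
                {"term": term, "level": level, "reference": False, "col": len(cols) - 1}
            )
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names, terms


def _logistic_pdf(x):
    # f = F (1 - F), computed stably
    F = special.expit(x)
    return F * (1.0 - F)


def _log_cell_prob(theta: np.ndarray, lin: np.ndarray, y: np.ndarray) -> np.ndarray:
    """log[F(theta_k - lin) - F(theta_{k-1} - lin)] for observed categories y."""
    K = theta.size + 1
    upper = np.where(y < K, theta[np.minimum(y, K - 1) - 1], np.inf)
    # y ranges 1..K; upper threshold index y-1 (theta_K = +inf)
    a = np.where(y < K, upper - lin, np.inf)
    b = np.where(y > 1, theta[np.maximum(y - 2, 0)] - lin, -np.inf)
    Fa = special.expit(a)
    Fb = special.expit(b)
    p = np.clip(Fa - Fb, 1e-300, 1.0)
    return np.log(p)


def _cell_derivs(theta, lin, y):
    """(d/du, d2/du2) of log p where u adds to lin with coefficient +1
    inside F(theta - lin - u); evaluated at the given lin."""
    K = theta.size + 1
    a = np.where(y < K, theta[np.minimum(y, K - 1) - 1] - lin, np.inf)
    b = np.where(y > 1, theta[np.maximum(y - 2, 0)] - lin, -np.inf)
    Fa, Fb = special.expit(a), special.expit(b)
    fa = np.where(np.isfinite(a), Fa * (1 - Fa), 0.0)
    fb = np.where(np.isfinite(b), Fb * (1 - Fb), 0.0)
    fpa = np.where(np.isfinite(a), fa * (1 - 2 * Fa), 0.0)
    fpb = np.where(np.isfinite(b), fb * (1 - 2 * Fb), 0.0)
    p = np.clip(Fa - Fb, 1e-300, 1.0)
    d1 = -(fa - fb) / p
    d2 = (fpa - fpb) / p - d1**2
    return d1, d2


def loglik_fixed(
    theta: np.ndarray, beta: np.ndarray, X: np.ndarray, y: np.ndarray
) -> float:
    """Fixed-effects proportional-odds log-likelihood."""
    return float(np.sum(_log_cell_prob(theta, X @ beta, y)))


def loglik_mixed(
    theta: np.ndarray,
    beta: np.ndarray,
    sigma_gamma: float,
    X: np.ndarray,
    y: np.ndarray,
    subject: np.ndarray,
    n_nodes: int = 15,
) -> float:
    """Marginal log-likelihood with a Gaussian random intercept per subject.

    The per-subject integral over gamma_j is evaluated by adaptive
    Gauss-Hermite quadrature: a Newton search locates each subject's
    posterior mode of the integrand, the local curvature sets the node
    scaling, and ``n_nodes`` Hermite nodes are laid out around the mode.
    Reduces exactly to :func:`loglik_fixed` at sigma_gamma = 0.
    """
    if not np.all(np.diff(theta) > 0):
        raise ValueError("thresholds must be strictly increasing")
    if sigma_gamma < 0:
        raise ValueError("sigma_gamma must be >= 0")
    if sigma_gamma < 1e-10:
        return loglik_fixed(theta, beta, X, y)

    lin = X @ beta if X.size else np.zeros(len(y))
    n_subj = int(subject.max()) + 1
    s2 = sigma_gamma**2

    # Newton search for the mode of h(u) = sum_i log p_i(u) - u^2/(2 s2)
    u = np.zeros(n_subj)
    for _ in range(50):
        d1, d2 = _cell_derivs(theta, lin + u[subject], y)
        g = np.bincount(subject, weights=d1, minlength=n_subj) - u / s2
        h = np.bincount(subject, weights=d2, minlength=n_subj) - 1.0 / s2
        step = g / h
        u_new = u - step
        if np.max(np.abs(step)) < 1e-10:
            u = u_new
            break
        u = u_new
    _, d2 = _cell_derivs(theta, lin + u[subject], y)
    h = np.bincount(subject, weights=d2, minlength=n_subj) - 1.0 / s2
    tau = 1.0 / np.sqrt(-h)

    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    log_terms = np.empty((n_nodes, n_subj))
    for q in range(n_nodes):
        uq = u + np.sqrt(2.0) * tau * nodes[q]
        lp = _log_cell_prob(theta, lin + uq[subject], y)
        per_subj = np.bincount(subject, weights=lp, minlength=n_subj)
        log_phi = -0.5 * np.log(2 * np.pi * s2) - uq**2 / (2 * s2)
        log_terms[q] = np.log(weights[q]) + nodes[q] ** 2 + per_subj + log_phi
    log_L = special.logsumexp(log_terms, axis=0) + 0.5 * np.log(2.0) + np.log(tau)
    if not np.all(np.isfinite(log_L)):
        bad = int(np.flatnonzero(~np.isfinite(log_L))[0])
        raise FloatingPointError(f"non-finite quadrature for subject index {bad}")
    return float(log_L.sum())


# ---------------------------------------------------------------------------
# fitting


@dataclasses.dataclass
class CumLogitFit:
    """Fitted proportional-odds model (mixed or fixed-effects)."""

    thresholds: np.ndarray          # theta_k, strictly increasing
    beta: np.ndarray
    beta_names: list[str]
    sigma_gamma: float              # 0 in the fixed-effects variant
    loglik: float
    aic: float
    cov: np.ndarray                 # Wald covariance of (theta, beta)
    term_info: list[dict]
    n_levels: int
    n_obs: int
    n_subjects: int | None
    random_intercept: bool

    def beta_se(self) -> np.ndarray:
        k = self.thresholds.size
        return np.sqrt(np.diag(self.cov)[k : k + self.beta.size])

    def threshold_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov)[: self.thresholds.size])


def _unpack_theta(raw: np.ndarray, K: int) -> np.ndarray:
    theta = np.empty(K - 1)
    theta[0] = raw[0]
    if K > 2:
        theta[1:] = raw[0] + np.cumsum(np.exp(raw[1 : K - 1]))
    return theta


def fit_cumlogit(
    table: pd.DataFrame,
    outcome: str = "response",
    covariates: Sequence[str] = ("measure_type", "motivation_target"),
    random_intercept: bool = True,
    subject_col: str = "respondent_id",
    references: Mapping[str, str] | None = None,
    n_nodes: int = 15,
) -> CumLogitFit:
    """Maximum-likelihood proportional-odds fit.

    With ``random_intercept`` the subject-level Gaussian intercept is
    integrated out by adaptive Gauss-Hermite quadrature; AIC counts
    thresholds, fixed effects, and (if present) the random-intercept
    variance.  Deterministic given the data.
    """
    y = table[outcome].to_numpy(dtype=int)
    levels = np.unique(y)
    if levels.size < 2:
        raise ValueError("outcome has a single observed level; no thresholds")
    K = int(levels.max())
    X, names, term_info = _build_X(table, covariates, references)

    # crude separation screen: a binary column perfectly splitting extremes
    for j in range(X.shape[1]):
        col = X[:, j]
        if set(np.unique(col)) <= {0.0, 1.0}:
            if (y[col == 1] == K).all() or (y[col == 1] == 1).all():
                warnings.warn(
                    f"possible separation on {names[j]!r}; estimates may drift",
                    SeparationWarning,
                )

    subject = None
    n_subjects = None
    if random_intercept:
        codes, _ = pd.factorize(table[subject_col], sort=True)
        subject = codes.astype(int)
        n_subjects = int(subject.max()) + 1

    # start: thresholds at empirical cumulative logits, beta = 0
    freqs = np.array([(y <= k).mean() for k in range(1, K)])
    freqs = np.clip(freqs, 0.01, 0.99)
    theta0 = special.logit(freqs)
    theta0 = np.maximum.accumulate(theta0 + 1e-6 * np.arange(K - 1))
    raw0 = [theta0[0]] + list(np.log(np.maximum(np.diff(theta0), 1e-3)))
    x0 = np.array(raw0 + [0.0] * X.shape[1] + ([0.0] if random_intercept else []))

    p = X.shape[1]

    def nll(v):
        theta = _unpack_theta(v, K)
        beta = v[K - 1 : K - 1 + p]
        try:
            if random_intercept:
                sig = float(np.exp(np.clip(v[-1], -15, 5)))
                return -loglik_mixed(theta, beta, sig, X, y, subject, n_nodes)
            return -loglik_fixed(theta, beta, X, y)
        except FloatingPointError:
            return np.inf

    res = optimize.minimize(
        nll, x0, method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-13, "gtol": 1e-8},
    )
    if not res.success and abs(res.fun) < 1e12:
        res2 = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                 options={"maxiter": 5000, "fatol": 1e-10})
        if res2.fun < res.fun:
            res = res2
    theta = _unpack_theta(res.x, K)
    beta = res.x[K - 1 : K - 1 + p]
    sigma = float(np.exp(np.clip(res.x[-1], -15, 5))) if random_intercept else 0.0
    ll = -float(res.fun)
    n_par = (K - 1) + p + (1 if random_intercept else 0)
    aic = -2.0 * ll + 2.0 * n_par

    # Wald covariance in the natural (theta, beta) parameterisation
    def nat_nll(v):
        th = v[: K - 1]
        be = v[K - 1 : K - 1 + p]
        if random_intercept:
            return -loglik_mixed(th, be, sigma, X, y, subject, n_nodes)
        return -loglik_fixed(th, be, X, y)

    from statsmodels.tools.numdiff import approx_hess

    nat = np.concatenate([theta, beta])
    H = approx_hess(nat, nat_nll)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)

    return CumLogitFit(
        thresholds=theta,
        beta=beta,
        beta_names=names,
        sigma_gamma=sigma,
        loglik=ll,
        aic=aic,
        cov=cov,
        term_info=term_info,
        n_levels=K,
        n_obs=len(y),
        n_subjects=n_subjects,
        random_intercept=random_intercept,
    )


def odds_ratios(fit: CumLogitFit) -> pd.DataFrame:
    """OR table: exp(estimate) with Wald 95% CI and p-value per row.

    Threshold rows are styled "Intercept 1|2" etc.; reference levels appear
    with OR 1.00 and dashes, matching the published layout.
    """
    rows = []
    th_se = fit.threshold_se()
    for k, (t, se) in enumerate(zip(fit.thresholds, th_se), start=1):
        z = t / se if se > 0 else np.inf
        rows.append(
            {
                "term": f"Intercept {k}|{k+1}",
                "OR": float(np.exp(t)),
                "ci_low": float(np.exp(t - 1.96 * se)),
                "ci_high": float(np.exp(t + 1.96 * se)),
                "p": float(2 * stats.norm.sf(abs(z))),
                "reference": False,
            }
        )
    be_se = fit.beta_se()
    for info in fit.term_info:
        label = (
            f"{info['term']} [{info['level']}]" if info["level"] else info["term"]
        )
        if info["reference"]:
            rows.append(
                {
                    "term": f"{label} (reference)",
                    "OR": 1.0,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p": np.nan,
                    "reference": True,
                }
            )
        else:
            b = fit.beta[info["col"]]
            se = be_se[info["col"]]
            z = b / se if se > 0 else np.inf
            rows.append(
                {
                    "term": label,
                    "OR": float(np.exp(b)),
                    "ci_low": float(np.exp(b - 1.96 * se)),
                    "ci_high": float(np.exp(b + 1.96 * se)),
                    "p": float(2 * stats.norm.sf(abs(z))),
                    "reference": False,
                }
            )
    return pd.DataFrame(rows)


def fit_conspiracy(
    data: SurveyDataset | pd.DataFrame,
    covariates: Sequence[str],
    references: Mapping[str, str] | None = None,
) -> tuple[CumLogitFit, pd.DataFrame]:
    """Fixed-effects proportional-odds model of the 1-7 conspiracy score."""
    df = data.table if isinstance(data, SurveyDataset) else data
    fit = fit_cumlogit(
        df,
        outcome="conspiracy",
        covariates=covariates,
        random_intercept=False,
        references=references,
    )
    return fit, odds_ratios(fit)


def forward_select_aic(
    table: pd.DataFrame,
    outcome: str,
    candidates: Sequence[str],
    random_intercept: bool = True,
    subject_col: str = "respondent_id",
    references: Mapping[str, str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Greedy AIC forward selection over candidate covariates."""
    selected: list[str] = []
    base = fit_cumlogit(
        table, outcome, selected, random_intercept, subject_col, references
    )
    cur = base.aic
    rows = [{"step": 0, "candidate": "(none)", "aic": cur, "selected": True}]
    remaining = list(candidates)
    step = 0
    while remaining:
        step += 1
        trials = []
        for cand in remaining:
            try:
                f = fit_cumlogit(
                    table, outcome, selected + [cand],
                    random_intercept, subject_col, references,
                )
                a = f.aic
            except (ValueError, np.linalg.LinAlgError):
                a = np.inf
            trials.append((cand, a))
            rows.append({"step": step, "candidate": cand, "aic": a, "selected": False})
        best_cand, best_aic = min(trials, key=lambda t: t[1])
        if best_aic >= cur:
            break
        selected.append(best_cand)
        cur = best_aic
        remaining.remove(best_cand)
        for r in rows:
            if r["step"] == step and r["candidate"] == best_cand:
                r["selected"] = True
    return selected, pd.DataFrame(rows)
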