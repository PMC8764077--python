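"""Bayesian bivariate Gaussian distributional regression.

The two 0-100 intention scores are modelled jointly as

    (Y1, Y2) ~ N2(mu, Sigma),   Sigma = D Omega D,

with D = diag(sigma1, sigma2) and Omega the 2x2 correlation matrix with
off-diagonal rho.  All five distribution parameters are regressed on
covariates through link functions:

    mu_j          = X beta_j            (identity)
    log(sigma_j)  = X gamma_j           (log)
    rhogit(rho)   = X beta_3,           rhogit(rho) = rho / sqrt(1 - rho^2)

Estimation is maximum likelihood (joint over all five coefficient blocks,
penalized for smooth terms) followed by blockwise adaptive random-walk
Metropolis MCMC started at the ML solution with flat priors; posterior
summaries are means and 2.5-97.5% percentile credible intervals.  Model
comparison uses the Deviance Information Criterion with a greedy forward
search that enters each candidate covariate into all five blocks at once.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .design import BLOCKS, DesignMatrices, DesignSpec, build_design

LOG2PI = float(np.log(2.0 * np.pi))


class ConvergenceError(RuntimeError):
    """ML optimisation failed; carries the scipy result as ``.trace``."""

    def __init__(self, msg: str, trace=None):
        super().__init__(msg)
        self.trace = trace


class RankError(ValueError):
    pass


class SamplerError(RuntimeError):
    pass


def rhogit(rho):
    """rhogit(rho) = rho / sqrt(1 - rho^2), a bijection (-1,1) -> R."""
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) >= 1):
        raise ValueError("rhogit requires |rho| < 1")
    out = rho / np.sqrt(1.0 - rho**2)
    return float(out) if out.ndim == 0 else out


def rhogit_inverse(eta):
    """Inverse link: eta -> eta / sqrt(1 + eta^2) in (-1, 1)."""
    eta = np.asarray(eta, dtype=float)
    out = eta / np.sqrt(1.0 + eta**2)
    return float(out) if out.ndim == 0 else out


@dataclasses.dataclass
class MCMCConfig:
    """Sampler settings; the published run used 10,000 iterations with a
    burn-in of 1,000 (adaptation happens during burn-in only)."""

    iterations: int = 10_000
    burnin: int = 1_000
    seed: int = 0
    adapt_interval: int = 50
    target_accept: float = 0.234

    def __post_init__(self):
        if not self.iterations > self.burnin >= 0:
            raise ValueError("require iterations > burnin >= 0")


class _Evaluator:
    """Joint log-likelihood, gradient, and per-observation terms.

    Operates on a single packed vector over the *free* blocks; ``fixed``
    blocks keep a constant coefficient vector (used for reduction tests and
    degenerate designs).
    """

    def __init__(
        self,
        y: np.ndarray,
        designs: DesignMatrices,
        lambdas: Mapping[str, float] | None = None,
        fixed: Mapping[str, np.ndarray] | None = None,
    ):
        self.y1 = y[:, 0]
        self.y2 = y[:, 1]
        self.designs = designs
        self.fixed = {k: np.asarray(v, dtype=float) for k, v in (fixed or {}).items()}
        self.free_blocks = [b for b in BLOCKS if b not in self.fixed]
        self.lambdas = dict(lambdas or {})
        self.slices: dict[str, slice] = {}
        off = 0
        for b in self.free_blocks:
            p = designs.X[b].shape[1]
            self.slices[b] = slice(off, off + p)
            off += p
        self.n_params = off

    def unpack(self, vec: np.ndarray) -> dict[str, np.ndarray]:
        out = dict(self.fixed)
        for b in self.free_blocks:
            out[b] = vec[self.slices[b]]
        return out

    def pack(self, params: Mapping[str, np.ndarray]) -> np.ndarray:
        return np.concatenate([np.asarray(params[b], float) for b in self.free_blocks])

    def etas(self, params: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
        return {b: self.designs.X[b] @ params[b] for b in BLOCKS}

    def _terms(self, etas):
        mu1, mu2 = etas["mu1"], etas["mu2"]
        ls1 = np.clip(etas["logsigma1"], -40.0, 40.0)
        ls2 = np.clip(etas["logsigma2"], -40.0, 40.0)
        s1, s2 = np.exp(ls1), np.exp(ls2)
        eta_r = etas["rhogit"]
        rho = eta_r / np.sqrt(1.0 + eta_r**2)
        r2 = 1.0 / (1.0 + eta_r**2)  # = 1 - rho^2
        z1 = (self.y1 - mu1) / s1
        z2 = (self.y2 - mu2) / s2
        return mu1, mu2, s1, s2, ls1, ls2, rho, r2, z1, z2

    def pointwise(self, etas) -> np.ndarray:
        _, _, _, _, ls1, ls2, rho, r2, z1, z2 = self._terms(etas)
        Q = (z1**2 - 2.0 * rho * z1 * z2 + z2**2) / r2
        return -LOG2PI - ls1 - ls2 - 0.5 * np.log(r2) - 0.5 * Q

    def penalty(self, params) -> float:
        pen = 0.0
        for b in BLOCKS:
            P = self.designs.penalties[b]
            if P is not None:
                lam = self.lambdas.get(b, 1.0)
                beta = params[b]
                pen += 0.5 * lam * float(beta @ P @ beta)
        return pen

    def loglik(self, vec: np.ndarray, penalized: bool = True) -> float:
        params = self.unpack(vec)
        ll = float(np.sum(self.pointwise(self.etas(params))))
        if not np.isfinite(ll):
            return -np.inf
        if penalized:
            ll -= self.penalty(params)
        return ll

    def grad(self, vec: np.ndarray, penalized: bool = True) -> np.ndarray:
        params = self.unpack(vec)
        etas = self.etas(params)
        _, _, s1, s2, _, _, rho, r2, z1, z2 = self._terms(etas)
        d = {
            "mu1": (z1 - rho * z2) / (s1 * r2),
            "mu2": (z2 - rho * z1) / (s2 * r2),
            "logsigma1": -1.0 + (z1**2 - rho * z1 * z2) / r2,
            "logsigma2": -1.0 + (z2**2 - rho * z1 * z2) / r2,
        }
        Qraw = z1**2 - 2.0 * rho * z1 * z2 + z2**2
        d_rho = rho / r2 + z1 * z2 / r2 - rho * Qraw / r2**2
        d["rhogit"] = d_rho * r2**1.5  # chain rule through the rhogit inverse
        g = np.empty(self.n_params)
        for b in self.free_blocks:
            gb = self.designs.X[b].T @ d[b]
            if penalized:
                P = self.designs.penalties[b]
                if P is not None:
                    gb = gb - self.lambdas.get(b, 1.0) * (P @ params[b])
            g[self.slices[b]] = gb
        return g

    def hessian(self, vec: np.ndarray, penalized: bool = True) -> np.ndarray:
        """Numerical Hessian by central differences of the analytic gradient."""
        p = self.n_params
        H = np.empty((p, p))
        h = 1e-5 * np.maximum(1.0, np.abs(vec))
        for i in range(p):
            e = np.zeros(p)
            e[i] = h[i]
            H[i] = (self.grad(vec + e, penalized) - self.grad(vec - e, penalized)) / (
                2.0 * h[i]
            )
        return (H + H.T) / 2.0


@dataclasses.dataclass
class BBGFit:
    """ML estimates (and, after sampling, the evaluator needed for MCMC)."""

    designs: DesignMatrices
    y: np.ndarray                       # (n, 2)
    responses: tuple[str, str]
    params: dict[str, np.ndarray]       # block -> coefficient vector
    loglik: float                       # unpenalized at the estimate
    penalized_loglik: float
    cov: np.ndarray                     # asymptotic covariance of free params
    names: list[str]                    # block-prefixed coefficient names
    lambdas: dict[str, float]
    evaluator: _Evaluator

    def vector(self) -> np.ndarray:
        return self.evaluator.pack(self.params)

    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def slices(self) -> dict[str, slice]:
        return self.evaluator.slices


def _check_rank(designs: DesignMatrices) -> None:
    for b in BLOCKS:
        X = designs.X[b]
        if X.shape[1] == 0:
            continue
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = diag < 1e-8 * max(diag.max(), 1.0)
        if bad.any():
            cols = [designs.columns[b][i] for i in np.flatnonzero(bad)]
            raise RankError(f"collinear column(s) in block {b!r}: {cols}")


def _default_init(ev: _Evaluator) -> np.ndarray:
    y1, y2 = ev.y1, ev.y2
    start = {}
    corr = np.corrcoef(y1, y2)[0, 1] if y1.size > 2 else 0.0
    corr = float(np.clip(np.nan_to_num(corr), -0.95, 0.95))
    intercepts = {
        "mu1": float(np.mean(y1)),
        "mu2": float(np.mean(y2)),
        "logsigma1": float(np.log(max(np.std(y1), 1e-3))),
        "logsigma2": float(np.log(max(np.std(y2), 1e-3))),
        "rhogit": rhogit(corr),
    }
    for b in ev.free_blocks:
        p = ev.designs.X[b].shape[1]
        v = np.zeros(p)
        if p > 0:
            v[0] = intercepts[b]
        start[b] = v
    return ev.pack(start)


def fit_ml(
    designs: DesignMatrices,
    y: np.ndarray,
    responses: tuple[str, str] = ("y1", "y2"),
    init: np.ndarray | None = None,
    lambdas: Mapping[str, float] | None = None,
    fixed: Mapping[str, np.ndarray] | None = None,
    select_lambda: bool = True,
    gtol: float = 1e-6,
) -> BBGFit:
    """Joint maximum-(penalized-)likelihood fit of all five blocks.

    When smooth terms are present and ``lambdas`` is not given, a single
    shared smoothing parameter is chosen on a log-spaced grid by a Laplace
    approximation to the marginal likelihood, then held fixed.
    """
    y = np.asarray(y, dtype=float)
    _check_rank(designs)
    has_penalty = any(designs.penalties[b] is not None for b in BLOCKS)

    if lambdas is None and has_penalty and select_lambda:
        lambdas = _select_lambda(designs, y, fixed=fixed)
    ev = _Evaluator(y, designs, lambdas=lambdas, fixed=fixed)
    x0 = _default_init(ev) if init is None else np.asarray(init, dtype=float)

    def nll(v):
        return -ev.loglik(v)

    def njac(v):
        return -ev.grad(v)

    res = optimize.minimize(
        nll, x0, jac=njac, method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-9},
    )
    gnorm = float(np.max(np.abs(ev.grad(res.x))))
    scale = max(1.0, abs(res.fun))
    if gnorm > gtol * scale:
        res2 = optimize.minimize(
            nll, res.x, jac=njac, method="BFGS",
            options={"maxiter": 1000, "gtol": gtol * scale / 10.0},
        )
        if res2.fun <= res.fun:
            res = res2
        gnorm = float(np.max(np.abs(ev.grad(res.x))))
    if not np.isfinite(res.fun) or gnorm > 1e-3 * scale:
        raise ConvergenceError(
            f"ML optimisation did not converge (max |grad| = {gnorm:.3g})",
            trace=res,
        )

    H = ev.hessian(res.x)
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(-H)
    params = ev.unpack(res.x)
    names = []
    for b in ev.free_blocks:
        names.extend(f"{b}:{c}" for c in designs.columns[b])
    return BBGFit(
        designs=designs,
        y=y,
        responses=tuple(responses),
        params=params,
        loglik=ev.loglik(res.x, penalized=False),
        penalized_loglik=float(-res.fun),
        cov=cov,
        names=names,
        lambdas=dict(ev.lambdas),
        evaluator=ev,
    )


def _select_lambda(
    designs: DesignMatrices,
    y: np.ndarray,
    grid: Sequence[float] = (1e-4, 1e-2, 1.0, 1e2, 1e4, 1e6),
    fixed: Mapping[str, np.ndarray] | None = None,
) -> dict[str, float]:
    """Shared smoothing parameter by a Laplace-approximate marginal likelihood."""
    pen_blocks = [b for b in BLOCKS if designs.penalties[b] is not None]
    best, best_score = grid[0], -np.inf
    init = None
    for lam in grid:
        lams = {b: lam for b in pen_blocks}
        try:
            fit = fit_ml(
                designs, y, lambdas=lams, fixed=fixed,
                select_lambda=False, init=init,
            )
        except ConvergenceError:
            continue
        init = fit.vector()
        ev = fit.evaluator
        H = ev.hessian(init)
        sign, logdet_h = np.linalg.slogdet(-H)
        if sign <= 0:
            continue
        logdet_p = 0.0
        for b in pen_blocks:
            P = designs.penalties[b]
            evals = np.linalg.eigvalsh(P)
            pos = evals[evals > 1e-10 * evals.max()]
            logdet_p += float(np.sum(np.log(lam * pos)))
        score = fit.penalized_loglik + 0.5 * logdet_p - 0.5 * logdet_h
        if score > best_score:
            best_score, best = score, lam
    return {b: best for b in pen_blocks}


@dataclasses.dataclass
class BBGDraws:
    """Retained posterior draws (after burn-in) plus sampler diagnostics."""

    draws: np.ndarray                   # (kept, p) over free blocks
    names: list[str]
    slices: dict[str, slice]
    acceptance: dict[str, float]
    config: MCMCConfig
    fit: BBGFit

    def block(self, name: str) -> np.ndarray:
        return self.draws[:, self.slices[name]]


def run_mcmc(fit: BBGFit, config: MCMCConfig | None = None) -> BBGDraws:
    """Blockwise adaptive random-walk Metropolis from the ML solution.

    Proposals for each coefficient block are Gaussian with covariance equal
    to that block's asymptotic ML covariance times an adapted scalar; priors
    are flat on all regression coefficients (the spline penalty acts as the
    only Gaussian prior, with its smoothing parameter fixed at the ML-stage
    value).  Adaptation runs during burn-in only, so the retained chain is a
    valid Markov chain.  Seed-deterministic.
    """
    config = config or MCMCConfig()
    ev = fit.evaluator
    rng = np.random.default_rng(config.seed)
    x = fit.vector().copy()
    p = x.size

    chol = {}
    scale = {}
    for b in ev.free_blocks:
        sl = ev.slices[b]
        pb = sl.stop - sl.start
        C = fit.cov[sl, sl]
        C = (C + C.T) / 2.0 + 1e-10 * np.eye(pb) * max(np.trace(C) / max(pb, 1), 1e-8)
        try:
            chol[b] = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            chol[b] = np.diag(np.sqrt(np.clip(np.diag(C), 1e-12, None)))
        scale[b] = 2.38 / np.sqrt(max(pb, 1))

    # incremental state: linear predictors per block
    etas = {b: ev.designs.X[b] @ ev.unpack(x)[b] for b in BLOCKS}
    cur_ll = float(np.sum(ev.pointwise(etas))) - ev.penalty(ev.unpack(x))

    kept = config.iterations - config.burnin
    draws = np.empty((kept, p))
    acc_count = {b: 0 for b in ev.free_blocks}
    win_count = {b: 0 for b in ev.free_blocks}
    win_acc = {b: 0 for b in ev.free_blocks}
    params = ev.unpack(x)

    for it in range(config.iterations):
        for b in ev.free_blocks:
            sl = ev.slices[b]
            pb = sl.stop - sl.start
            step = scale[b] * (chol[b] @ rng.standard_normal(pb))
            new_beta = params[b] + step
            new_eta = ev.designs.X[b] @ new_beta
            old_eta, old_beta = etas[b], params[b]
            etas[b], params[b] = new_eta, new_beta
            new_ll = float(np.sum(ev.pointwise(etas))) - ev.penalty(params)
            if np.isfinite(new_ll) and np.log(rng.uniform()) < new_ll - cur_ll:
                cur_ll = new_ll
                x[sl] = new_beta
                acc_count[b] += 1
                win_acc[b] += 1
            else:
                etas[b], params[b] = old_eta, old_beta
            win_count[b] += 1

        if it < config.burnin and (it + 1) % config.adapt_interval == 0:
            for b in ev.free_blocks:
                rate = win_acc[b] / max(win_count[b], 1)
                scale[b] *= float(np.exp(rate - config.target_accept))
                scale[b] = float(np.clip(scale[b], 1e-4, 50.0))
                win_acc[b] = win_count[b] = 0
        if it >= config.burnin:
            draws[it - config.burnin] = x

    acceptance = {
        b: acc_count[b] / config.iterations for b in ev.free_blocks
    }
    if any(r < 0.01 for r in acceptance.values()):
        worst = min(acceptance, key=acceptance.get)
        raise SamplerError(
            f"acceptance rate {acceptance[worst]:.3%} in block {worst!r} "
            "after adaptation"
        )
    return BBGDraws(
        draws=draws, names=fit.names, slices=dict(ev.slices),
        acceptance=acceptance, config=config, fit=fit,
    )


@dataclasses.dataclass
class PosteriorSummary:
    """Posterior mean and 95% credible interval per coefficient."""

    table: pd.DataFrame  # columns: name, mean, q2.5, q97.5, excl_zero
    dic: float | None = None


def summarize(draws: BBGDraws, dic_value: float | None = None) -> PosteriorSummary:
    """Posterior mean and 2.5-97.5% percentile interval per coefficient;
    ``excl_zero`` flags intervals excluding zero (the tables' bold rows)."""
    if draws.draws.shape[0] < 100:
        raise ValueError("need at least 100 retained draws to summarise")
    mean = draws.draws.mean(axis=0)
    lo, hi = np.percentile(draws.draws, [2.5, 97.5], axis=0)
    table = pd.DataFrame(
        {
            "name": draws.names,
            "mean": mean,
            "q2.5": lo,
            "q97.5": hi,
            "excl_zero": (lo > 0) | (hi < 0),
        }
    )
    return PosteriorSummary(table=table, dic=dic_value)


def dic(draws: BBGDraws, max_draws: int = 4000) -> float:
    """Deviance Information Criterion: DIC = Dbar + pD, pD = Dbar - D(theta_bar).

    The deviance uses the unpenalized likelihood.  ``max_draws`` thins the
    chain evenly for the posterior-mean deviance.
    """
    ev = draws.fit.evaluator
    D = draws.draws
    if D.shape[0] > max_draws:
        idx = np.linspace(0, D.shape[0] - 1, max_draws).astype(int)
        D = D[idx]
    devs = np.array([-2.0 * ev.loglik(v, penalized=False) for v in D])
    dbar = float(devs.mean())
    d_at_mean = -2.0 * ev.loglik(D.mean(axis=0), penalized=False)
    pd_eff = dbar - d_at_mean
    return dbar + pd_eff


def fit_and_dic(
    spec: DesignSpec,
    data: pd.DataFrame,
    responses: tuple[str, str],
    config: MCMCConfig,
) -> tuple[BBGFit, BBGDraws, float]:
    designs = build_design(spec, data)
    y = data[list(responses)].to_numpy(dtype=float)
    fit = fit_ml(designs, y, responses=responses)
    draws = run_mcmc(fit, config)
    return fit, draws, dic(draws)


def forward_select(
    candidates: Sequence[str],
    data: pd.DataFrame,
    responses: tuple[str, str] = ("vaccine_intent", "cta_intent"),
    config: MCMCConfig | None = None,
    base_spec: DesignSpec | None = None,
    references: Mapping[str, str] | None = None,
    tie_tol: float = 0.01,
) -> tuple[DesignSpec, pd.DataFrame]:
    """Greedy DIC forward selection, entering candidates in all five blocks.

    At each step every remaining candidate is added (simultaneously to the
    mean, scale, and correlation predictors), the model refitted and
    resampled, and the candidate with the lowest DIC enters if it improves
    on the current model; ties within ``tie_tol`` go to the earlier-listed
    candidate.  Returns the selected spec and the full selection trace.
    """
    config = config or MCMCConfig()
    spec = base_spec or DesignSpec.shared([], references=references)
    _, _, cur_dic = fit_and_dic(spec, data, responses, config)
    remaining = list(candidates)
    rows = [
        {"step": 0, "candidate": "(intercept only)", "dic": cur_dic, "selected": True}
    ]
    step = 0
    while remaining:
        step += 1
        trials = []
        for cand in remaining:
            try:
                _, _, d = fit_and_dic(spec.with_term(cand), data, responses, config)
            except (ConvergenceError, RankError, SamplerError):
                d = np.inf
            trials.append((cand, d))
            rows.append(
                {"step": step, "candidate": cand, "dic": d, "selected": False}
            )
        best_dic = min(d for _, d in trials)
        # earliest-listed candidate within the tie tolerance of the best
        winner = next(c for c, d in trials if d <= best_dic + tie_tol)
        winner_dic = dict(trials)[winner]
        if winner_dic >= cur_dic:
            break
        spec = spec.with_term(winner)
        cur_dic = winner_dic
        remaining.remove(winner)
        for r in rows:
            if r["step"] == step and r["candidate"] == winner:
                r["selected"] = True
    return spec, pd.DataFrame(rows)


def spline_effect(
    draws: BBGDraws,
    block: str,
    variable: str,
    grid: np.ndarray | None = None,
    n_grid: int = 100,
) -> pd.DataFrame:
    """Posterior mean curve and 95% CrI band of a fitted smooth on a grid.

    The smooth is centred (sum-to-zero over the fitting sample), so the
    curve reads as a deviation from the block's overall level.
    """
    basis = draws.fit.designs.splines[variable]
    lo, hi = basis.x_range
    if grid is None:
        grid = np.linspace(lo, hi, n_grid)
    grid = np.asarray(grid, dtype=float)
    B = basis.evaluate(grid)
    sl = draws.fit.designs.spline_slice(block, variable)
    block_draws = draws.block(block)[:, sl]
    curves = block_draws @ B.T  # (kept, grid)
    mean = curves.mean(axis=0)
    q_lo, q_hi = np.percentile(curves, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {variable: grid, "mean": mean, "q2.5": q_lo, "q97.5": q_hi}
    )
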