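"""Assembly of fitted results into the published table layouts.

The coefficient table groups the three reported blocks (two means and the
rhogit-correlation) by covariate, prints category interval bounds in the row
labels, marks credible intervals excluding zero with an asterisk (the bold
convention of the source tables), and footnotes the reference categories.
All plot data are also emitted as tables so nothing downstream parses
images.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .bbg import BBGDraws, PosteriorSummary
from .factors import CategoricalCoding


def _fmt(v: float) -> str:
    return f"{v:.2f}"


def render_table2(
    summary: PosteriorSummary,
    codings: dict[str, CategoricalCoding] | None = None,
    blocks: tuple[str, str, str] = ("mu1", "mu2", "rhogit"),
    block_titles: tuple[str, str, str] = (
        "COVID-19 vaccine", "CTA Immuni", "rhogit(rho)"
    ),
    references: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Coefficient table in the three-block layout plus footnote lines.

    One row per coefficient; columns per block give the posterior mean and
    95% CrI, with ``*`` marking intervals excluding zero.  Rows for
    categorical covariates carry the printed interval bounds from
    ``codings``; reference categories never appear as rows, only in the
    footnote.
    """
    codings = codings or {}
    tab = summary.table.set_index("name")
    # coefficient names look like "block:term" or "block:term[level]"
    row_keys: list[str] = []
    for name in tab.index:
        block, _, coef = name.partition(":")
        if block == blocks[0]:
            row_keys.append(coef)

    bound_labels: dict[str, str] = {}
    for coding in codings.values():
        labels = coding.formatted_labels()
        for plain, pretty in zip(coding.labels, labels):
            bound_labels[f"{coding.variable}[{plain}]"] = (
                f"{coding.variable}: {pretty}"
            )

    rows = []
    for coef in row_keys:
        row = {"term": bound_labels.get(coef, coef)}
        for block, title in zip(blocks, block_titles):
            name = f"{block}:{coef}"
            if name in tab.index:
                r = tab.loc[name]
                star = "*" if bool(r["excl_zero"]) else ""
                row[title] = f"{_fmt(r['mean'])}{star}"
                row[f"{title} 95% CrI"] = (
                    f"({_fmt(r['q2.5'])}, {_fmt(r['q97.5'])})"
                )
            else:
                row[title] = "-"
                row[f"{title} 95% CrI"] = "-"
        rows.append(row)
    table = pd.DataFrame(rows)

    footnotes = ["* 95% CrI outside the null effect."]
    if references:
        refs = "; ".join(f"{var} ({lev})" for var, lev in references.items())
        footnotes.append(f"Reference categories: {refs}.")
    if summary.dic is not None:
        footnotes.append(f"DIC = {summary.dic:.1f}.")
    return table, footnotes


def render_table3(or_table: pd.DataFrame) -> pd.DataFrame:
    """OR table with reference rows printed as ``1.00 - -``."""
    rows = []
    for _, r in or_table.iterrows():
        if r["reference"]:
            rows.append({"term": r["term"], "OR": "1.00", "95% CI": "-", "p": "-"})
        else:
            p = r["p"]
            p_str = "< 0.001" if p < 0.001 else f"{p:.3f}"
            rows.append(
                {
                    "term": r["term"],
                    "OR": _fmt(r["OR"]),
                    "95% CI": f"({_fmt(r['ci_low'])}-{_fmt(r['ci_high'])})",
                    "p": p_str,
                }
            )
    return pd.DataFrame(rows)


def residual_qq(draws: BBGDraws) -> pd.DataFrame:
    """Q-Q table of whitened a-posteriori residuals.

    Each observation's residual pair is standardised by the Cholesky factor
    of its fitted covariance at the posterior-mean parameters; under a
    correct model the pooled residuals are standard normal and the Q-Q
    slope is 1.  Returns sorted residuals against normal quantiles.
    """
    fit = draws.fit
    ev = fit.evaluator
    mean_params = ev.unpack(draws.draws.mean(axis=0))
    etas = {b: fit.designs.X[b] @ mean_params[b] for b in ev.designs.X}
    mu1, mu2 = etas["mu1"], etas["mu2"]
    s1 = np.exp(etas["logsigma1"])
    s2 = np.exp(etas["logsigma2"])
    eta_r = etas["rhogit"]
    rho = eta_r / np.sqrt(1.0 + eta_r**2)

    e1 = fit.y[:, 0] - mu1
    e2 = fit.y[:, 1] - mu2
    # inverse Cholesky whitening of each 2x2 covariance
    r1 = e1 / s1
    r2 = (e2 / s2 - rho * r1) / np.sqrt(1.0 - rho**2)
    resid = np.sort(np.concatenate([r1, r2]))
    n = resid.size
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return pd.DataFrame({"theoretical": theo, "observed": resid})


def qq_slope(qq: pd.DataFrame) -> float:
    """Robust Q-Q slope (quartile-based), ~1 for well-calibrated residuals."""
    x = qq["theoretical"].to_numpy()
    y = qq["observed"].to_numpy()
    xq = np.percentile(x, [25, 75])
    yq = np.percentile(y, [25, 75])
    return float((yq[1] - yq[0]) / (xq[1] - xq[0]))


def whitened_pair_correlation(draws: BBGDraws) -> float:
    """Correlation between the two whitened residual components; ~0 when the
    fitted correlation structure is right."""
    fit = draws.fit
    ev = fit.evaluator
    mean_params = ev.unpack(draws.draws.mean(axis=0))
    etas = {b: fit.designs.X[b] @ mean_params[b] for b in ev.designs.X}
    s1 = np.exp(etas["logsigma1"])
    s2 = np.exp(etas["logsigma2"])
    eta_r = etas["rhogit"]
    rho = eta_r / np.sqrt(1.0 + eta_r**2)
    r1 = (fit.y[:, 0] - etas["mu1"]) / s1
    r2 = ((fit.y[:, 1] - etas["mu2"]) / s2 - rho * r1) / np.sqrt(1.0 - rho**2)
    return float(np.corrcoef(r1, r2)[0, 1])
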