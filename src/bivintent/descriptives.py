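"""Descriptive layer: stratified summary tables and nonparametric tests.

Continuous variables are summarised as median (IQR) and compared across
strata by Wilcoxon rank-sum (2 strata) or Kruskal-Wallis (>2); categorical
variables as N (%) compared by the chi-squared test, switching to Fisher's
exact test whenever any expected cell count falls below 10.  Pairwise
monotone association uses Spearman's rank correlation with midrank ties.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

EXPECTED_COUNT_THRESHOLD = 10.0


class DegenerateTestWarning(UserWarning):
    pass


def needs_fisher(observed: np.ndarray) -> bool:
    """The switching rule: Fisher's exact test when any expected frequency
    in the contingency table is below 10.  Pure function of the table."""
    observed = np.asarray(observed, dtype=float)
    total = observed.sum()
    if total == 0:
        return True
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / total
    return bool((expected < EXPECTED_COUNT_THRESHOLD).any())


def _fisher_pvalue(
    observed: np.ndarray, rng: np.random.Generator | None = None,
    n_mc: int = 20000,
) -> float:
    """Fisher's exact p; exact for 2x2, Monte-Carlo (conditional on margins,
    probability-ordered) for larger tables."""
    observed = np.asarray(observed, dtype=int)
    if observed.shape == (2, 2):
        return float(stats.fisher_exact(observed)[1])
    rng = rng or np.random.default_rng(0)
    rows = np.repeat(np.arange(observed.shape[0]), observed.sum(axis=1))
    cols = np.repeat(np.arange(observed.shape[1]), observed.sum(axis=0))

    # conditional table probability given margins is proportional to
    # 1 / prod(n_ij!), so -sum(log n_ij!) orders tables by probability
    from scipy.special import gammaln

    def table_logp(tab):
        return -gammaln(tab + 1).sum()

    obs_stat = table_logp(observed)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(cols)
        tab = np.zeros_like(observed)
        np.add.at(tab, (rows, perm), 1)
        if table_logp(tab) <= obs_stat + 1e-12:
            hits += 1
    return (hits + 1) / (n_mc + 1)


def categorical_test(
    observed: np.ndarray, correction: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[str, float, float]:
    """(test name, statistic, p) with the chi-squared/Fisher switch applied."""
    observed = np.asarray(observed, dtype=float)
    if needs_fisher(observed):
        p = _fisher_pvalue(observed.astype(int), rng=rng)
        return "Fisher's exact", np.nan, p
    stat, p, _, _ = stats.chi2_contingency(observed, correction=correction)
    return "Pearson's chi-squared", float(stat), float(p)


def continuous_test(groups: Sequence[np.ndarray]) -> tuple[str, float, float]:
    """(test name, statistic, p): rank-sum for 2 strata, Kruskal-Wallis beyond."""
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty strata")
    if all(np.ptp(np.concatenate(groups)) == 0 for _ in (0,)):
        warnings.warn("all values identical across strata", DegenerateTestWarning)
        return ("degenerate", np.nan, 1.0)
    if len(groups) == 2:
        stat, p = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return "Wilcoxon rank-sum", float(stat), float(p)
    stat, p = stats.kruskal(*groups)
    return "Kruskal-Wallis", float(stat), float(p)


@dataclasses.dataclass
class StratifiedSummary:
    """One table row-block: the variable, per-stratum summary, and the test."""

    variable: str
    kind: str                      # "continuous" | "categorical"
    summary: pd.DataFrame          # rows: levels or single row; cols: strata
    test: str
    statistic: float
    p_value: float


def _fmt_median_iqr(x: np.ndarray) -> str:
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    return f"{med:g} ({q25:g}, {q75:g})"


def table_one(
    data: pd.DataFrame,
    group: str,
    continuous: Sequence[str],
    categorical: Sequence[str],
    seed: int = 0,
) -> list[StratifiedSummary]:
    """Stratified characteristics table with tests, one block per variable.

    Continuous rows show median (q25, q75); categorical rows show N (%)
    within each stratum (percentages sum to 100 per stratum up to rounding).
    """
    strata = list(pd.unique(data[group].astype(str)))
    if len(strata) < 2:
        raise ValueError(f"grouping variable {group!r} has < 2 observed levels")
    rng = np.random.default_rng(seed)
    out: list[StratifiedSummary] = []

    for var in continuous:
        cols = {"Overall": _fmt_median_iqr(data[var].to_numpy(float))}
        groups = []
        for s in strata:
            vals = data.loc[data[group].astype(str) == s, var].to_numpy(float)
            if len(vals) == 0:
                warnings.warn(f"empty stratum {s!r} for {var!r}; test skipped",
                              DegenerateTestWarning)
                cols[s] = "-"
                continue
            cols[s] = _fmt_median_iqr(vals)
            groups.append(vals)
        if len(groups) >= 2:
            name, stat, p = continuous_test(groups)
        else:
            name, stat, p = "skipped", np.nan, np.nan
        out.append(
            StratifiedSummary(
                variable=var, kind="continuous",
                summary=pd.DataFrame([cols], index=[var]),
                test=name, statistic=stat, p_value=p,
            )
        )

    for var in categorical:
        ct = pd.crosstab(data[var].astype(str), data[group].astype(str))
        ct = ct.reindex(columns=strata, fill_value=0)
        disp = ct.copy().astype(object)
        overall = ct.sum(axis=1)
        for s in strata:
            tot = ct[s].sum()
            disp[s] = [
                f"{v} ({100 * v / tot:.0f}%)" if tot else "-" for v in ct[s]
            ]
        disp.insert(
            0, "Overall",
            [f"{v} ({100 * v / overall.sum():.0f}%)" for v in overall],
        )
        nonempty = ct.loc[:, ct.sum(axis=0) > 0]
        if nonempty.shape[1] >= 2 and nonempty.shape[0] >= 2:
            name, stat, p = categorical_test(nonempty.to_numpy(), rng=rng)
        else:
            warnings.warn(f"degenerate table for {var!r}; test skipped",
                          DegenerateTestWarning)
            name, stat, p = "skipped", np.nan, np.nan
        out.append(
            StratifiedSummary(
                variable=var, kind="categorical", summary=disp,
                test=name, statistic=stat, p_value=p,
            )
        )
    return out


def summaries_to_frame(blocks: list[StratifiedSummary]) -> pd.DataFrame:
    """Flatten summary blocks into one printable table."""
    rows = []
    for b in blocks:
        first = True
        for idx, r in b.summary.iterrows():
            rows.append(
                {
                    "variable": b.variable if first else "",
                    "level": str(idx) if b.kind == "categorical" else "",
                    **r.to_dict(),
                    "test": b.test if first else "",
                    "p": f"{b.p_value:.3g}" if first and np.isfinite(b.p_value) else "",
                }
            )
            first = False
    return pd.DataFrame(rows)


def spearman_matrix(
    data: pd.DataFrame, variables: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho (midrank ties) and rho-test p-values."""
    k = len(variables)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x = data[variables[i]].to_numpy(float)
            y = data[variables[j]].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                raise ValueError(
                    f"fewer than 3 complete pairs for "
                    f"({variables[i]}, {variables[j]})"
                )
            if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                warnings.warn(
                    f"constant variable in pair ({variables[i]}, {variables[j]}); "
                    "correlation undefined", DegenerateTestWarning,
                )
                rho[i, j] = rho[j, i] = np.nan
                pval[i, j] = pval[j, i] = np.nan
                continue
            r, p = stats.spearmanr(x[ok], y[ok])
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    idx = list(variables)
    return (
        pd.DataFrame(rho, index=idx, columns=idx),
        pd.DataFrame(pval, index=idx, columns=idx),
    )


def paired_wilcoxon(
    x: np.ndarray, y: np.ndarray, zero_method: str = "wilcox",
    correction: bool = False,
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on within-respondent differences.

    Zero differences are dropped (the standard convention); all-zero input
    degenerates to p = 1 with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    d = x - y
    if np.all(d == 0):
        warnings.warn("all paired differences are zero", DegenerateTestWarning)
        return 0.0, 1.0
    stat, p = stats.wilcoxon(
        x, y, zero_method=zero_method, correction=correction
    )
    return float(stat), float(p)


def unpaired_wilcoxon(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Rank-sum variant for independent samples."""
    stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(stat), float(p)
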