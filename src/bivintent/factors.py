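"""Single-factor indices and categorical codings.

Two attitude dimensions — COVID-19 perceived risk and trust in politics and
science — are each measured by a 3-item block of 0-100 scores.  Each block is
summarised by a one-factor maximum-likelihood solution on the empirical
variance-covariance matrix; respondents then receive regression (Thomson)
factor scores, which are cut into terciles for use as categorical model
covariates.  The vaccine-doubts score gets a dedicated coder with a
zero-inflation ("no doubts") class plus terciles of the positive remainder.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import optimize


class FactorEstimationError(RuntimeError):
    pass


class HeywoodWarning(UserWarning):
    """A uniqueness hit its lower floor during estimation."""


class DegenerateCodingWarning(UserWarning):
    pass


@dataclasses.dataclass
class FactorModel:
    """One-factor solution on a 3-item block.

    ``variance_explained`` is sum(loading^2) / trace(S), with S the item
    covariance matrix on the fitting sample.
    """

    item_names: list[str]
    loadings: np.ndarray            # (3,)
    uniquenesses: np.ndarray        # (3,) positive
    variance_explained: float
    score_coefficients: np.ndarray  # (3,) regression-score weights
    centering: np.ndarray           # item means
    scaling: np.ndarray             # item sds (correlation mode) or ones

    def implied_covariance(self) -> np.ndarray:
        lam = self.loadings
        return np.outer(lam, lam) + np.diag(self.uniquenesses)


@dataclasses.dataclass
class CategoricalCoding:
    """Map from a continuous score to ordered labelled intervals.

    Intervals are lower-open / upper-closed, ``(lower, upper]``; the first
    interval additionally includes its lower bound so every observed value
    maps to exactly one category.  ``zero_inflated`` marks a leading
    point-mass class at exactly zero.
    """

    variable: str
    labels: list[str]
    bounds: list[tuple[float, float]]  # (lower, upper] per category
    zero_inflated: bool = False

    def assign(self, values: np.ndarray | pd.Series) -> pd.Categorical:
        vals = np.asarray(values, dtype=float)
        out = np.empty(vals.shape, dtype=object)
        start = 0
        if self.zero_inflated:
            out[vals == 0] = self.labels[0]
            start = 1
        for i in range(start, len(self.labels)):
            lo, hi = self.bounds[i]
            mask = (vals > lo) & (vals <= hi)
            if i == start:  # first interval is closed on the left
                mask |= vals == lo
            if self.zero_inflated:
                mask &= vals > 0
            out[mask] = self.labels[i]
        if (out == None).any():  # noqa: E711 - object array sentinel
            bad = vals[np.equal(out, None)][0]
            raise ValueError(
                f"value {bad!r} of {self.variable!r} falls outside every interval"
            )
        return pd.Categorical(out, categories=self.labels, ordered=True)

    def formatted_labels(self, digits: int = 3) -> list[str]:
        """Labels with printed interval bounds, e.g. ``Medium (-0.407, 0.623)``."""
        out = []
        start = 0
        if self.zero_inflated:
            out.append(self.labels[0])
            start = 1
        for i in range(start, len(self.labels)):
            lo, hi = self.bounds[i]
            out.append(f"{self.labels[i]} ({lo:.{digits}g}, {hi:.{digits}g})")
        return out


def _ml_discrepancy(params: np.ndarray, S: np.ndarray) -> float:
    """ML factor-analysis discrepancy F = log|Sigma| + tr(S Sigma^-1) - log|S| - p."""
    p = S.shape[0]
    lam = params[:p]
    psi = np.exp(params[p:])
    sigma = np.outer(lam, lam) + np.diag(psi)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    _, logdet_s = np.linalg.slogdet(S)
    return float(logdet + np.trace(S @ np.linalg.inv(sigma)) - logdet_s - p)


def fit_single_factor(
    items: pd.DataFrame | np.ndarray,
    standardize: bool = False,
    heywood_floor: float = 1e-3,
) -> FactorModel:
    """Maximum-likelihood one-factor solution on the empirical covariance matrix.

    Parameters
    ----------
    items : n x 3 table of scores
    standardize : bool
        If True, fit on the correlation matrix (items scaled to unit sd);
        default is the covariance-based fit.
    heywood_floor : float
        Uniquenesses are floored at ``heywood_floor * item variance``; hitting
        the floor emits :class:`HeywoodWarning`.

    Returns
    -------
    FactorModel with the loading sign fixed so the loading sum is positive.
    """
    if isinstance(items, pd.DataFrame):
        names = list(items.columns)
        X = items.to_numpy(dtype=float)
    else:
        X = np.asarray(items, dtype=float)
        names = [f"item{i+1}" for i in range(X.shape[1])]
    n, p = X.shape
    if p != 3:
        raise ValueError(f"expected a 3-item block, got {p} columns")
    if n < 10:
        raise FactorEstimationError(f"need at least 10 rows, got {n}")

    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    scale = sd if standardize else np.ones(p)
    Xs = (X - mu) / scale
    S = np.cov(Xs, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(S, tol=1e-10 * np.trace(S)) < p:
        raise FactorEstimationError("singular item covariance matrix")

    # principal-axis start
    w, V = np.linalg.eigh(S)
    lam0 = V[:, -1] * np.sqrt(w[-1])
    psi0 = np.clip(np.diag(S) - lam0**2, 1e-3 * np.diag(S), None)
    x0 = np.concatenate([lam0, np.log(psi0)])

    res = optimize.minimize(
        _ml_discrepancy, x0, args=(S,), method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000},
    )
    res = optimize.minimize(
        _ml_discrepancy, res.x, args=(S,), method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000},
    )
    if not np.isfinite(res.fun):
        raise FactorEstimationError("one-factor ML estimation did not converge")

    lam = res.x[:p]
    psi = np.exp(res.x[p:])
    floor = heywood_floor * np.diag(S)
    if (psi < floor).any():
        warnings.warn(
            "Heywood case: uniqueness floored at "
            f"{heywood_floor:g} x item variance", HeywoodWarning,
        )
        psi = np.maximum(psi, floor)
    if lam.sum() < 0:
        lam = -lam

    sigma = np.outer(lam, lam) + np.diag(psi)
    coeff = np.linalg.solve(sigma, lam)  # Thomson regression weights
    return FactorModel(
        item_names=names,
        loadings=lam,
        uniquenesses=psi,
        variance_explained=float((lam**2).sum() / np.trace(S)),
        score_coefficients=coeff,
        centering=mu,
        scaling=scale,
    )


def compute_scores(
    model: FactorModel, items: pd.DataFrame | np.ndarray
) -> np.ndarray:
    """Regression (Thomson) factor scores; mean ~ 0 over the fitting sample."""
    if isinstance(items, pd.DataFrame):
        if list(items.columns) != model.item_names:
            raise ValueError(
                f"item columns {list(items.columns)} do not match the fitted "
                f"block {model.item_names}"
            )
        X = items.to_numpy(dtype=float)
    else:
        X = np.asarray(items, dtype=float)
        if X.shape[1] != len(model.item_names):
            raise ValueError("item column count does not match the fitted block")
    Xs = (X - model.centering) / model.scaling
    return Xs @ model.score_coefficients


def _terciles(values: np.ndarray) -> tuple[float, float]:
    """Empirical 1/3 and 2/3 quantiles by the inverse-ECDF rule."""
    q1 = float(np.quantile(values, 1 / 3, method="inverted_cdf"))
    q2 = float(np.quantile(values, 2 / 3, method="inverted_cdf"))
    return q1, q2


def categorize_terciles(
    scores: np.ndarray | pd.Series,
    labels: tuple[str, str, str] = ("Low", "Medium", "High"),
    variable: str = "score",
    bounds: tuple[float, float] | None = None,
) -> tuple[CategoricalCoding, pd.Categorical]:
    """Cut scores into Low/Medium/High at the empirical tercile bounds.

    Intervals are lower-open/upper-closed; boundary values fall into the
    lower-indexed category.  ``bounds`` overrides the empirical quantiles
    (used to reproduce a published coding exactly).
    """
    vals = np.asarray(scores, dtype=float)
    if vals.size < 3:
        raise ValueError("need at least 3 scores for terciles")
    if np.ptp(vals) == 0:
        warnings.warn(
            f"all {variable!r} scores identical; single degenerate category",
            DegenerateCodingWarning,
        )
        coding = CategoricalCoding(
            variable=variable, labels=[labels[0]],
            bounds=[(float(vals[0]), float(vals[0]))],
        )
        return coding, coding.assign(vals)
    q1, q2 = bounds if bounds is not None else _terciles(vals)
    for q in (q1, q2):
        if (vals == q).sum() > vals.size / 3:
            warnings.warn(
                f"more than n/3 ties at tercile boundary {q:g} of {variable!r}; "
                "categories may be unbalanced", DegenerateCodingWarning,
            )
    coding = CategoricalCoding(
        variable=variable,
        labels=list(labels),
        bounds=[(float(vals.min()), q1), (q1, q2), (q2, float(vals.max()))],
    )
    return coding, coding.assign(vals)


def categorize_doubts(
    doubts: np.ndarray | pd.Series,
    labels: tuple[str, str, str, str] = ("No doubts", "Low", "Medium", "High"),
    variable: str = "vaccine_doubts",
) -> tuple[CategoricalCoding, pd.Categorical]:
    """Zero-inflated coding of the 0-100 vaccine-doubts score.

    Exact zeros form the "No doubts" class; the strictly positive values are
    cut at their own terciles into Low/Medium/High.
    """
    vals = np.asarray(doubts, dtype=float)
    if ((vals < 0) | (vals > 100)).any():
        raise ValueError("doubts scores must lie in [0, 100]")
    pos = vals[vals > 0]
    if (vals == 0).sum() == 0:
        warnings.warn(
            "no exact-zero doubts scores; 'No doubts' category is empty",
            DegenerateCodingWarning,
        )
    if pos.size < 3:
        raise ValueError("need at least 3 positive doubts scores for terciles")
    q1, q2 = _terciles(pos)
    coding = CategoricalCoding(
        variable=variable,
        labels=list(labels),
        bounds=[
            (0.0, 0.0),
            (float(pos.min()), q1),
            (q1, q2),
            (q2, float(pos.max())),
        ],
        zero_inflated=True,
    )
    return coding, coding.assign(vals)
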