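"""Design-matrix construction for the five distributional-regression blocks.

Each of the model parameters (two means, two log-scales, and the
rhogit-transformed correlation) gets its own design matrix built from a list
of terms.  A term is a numeric column, a categorical column (treatment-coded
against an explicit reference level), or a smooth ``s(variable)`` expanded
through a constrained thin-plate basis.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .splines import SplineBasis, build_spline_basis

BLOCKS = ("mu1", "mu2", "logsigma1", "logsigma2", "rhogit")

#: reference levels used throughout the published tables
DEFAULT_REFERENCES: dict[str, str] = {
    "doubts_cat": "No doubts",
    "risk_cat": "Low",
    "trust_cat": "Low",
    "gender": "female",
    "job": "employee",
    "education": "middle school",
    "conspiracy_cat": "Low",
    "salary": "unknown",
}


class CodingError(ValueError):
    """A factor level unseen at fit time appeared at prediction time."""


def is_spline_term(term: str) -> bool:
    return term.startswith("s(") and term.endswith(")")


def spline_variable(term: str) -> str:
    return term[2:-1]


@dataclasses.dataclass
class DesignSpec:
    """Per-block covariate term lists for the bivariate distributional model.

    ``terms[block]`` lists the terms entering that block's linear predictor
    (the intercept is implicit).  By default every block shares one list,
    mirroring the convention of entering the same covariates in all five
    parameters.
    """

    terms: dict[str, list[str]]
    references: dict[str, str] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_REFERENCES)
    )
    spline_bases: dict[str, int] = dataclasses.field(default_factory=dict)

    @classmethod
    def shared(
        cls,
        covariates: Sequence[str],
        references: Mapping[str, str] | None = None,
        spline_bases: Mapping[str, int] | None = None,
    ) -> "DesignSpec":
        """One covariate list applied to all five parameter blocks."""
        refs = dict(DEFAULT_REFERENCES)
        if references:
            refs.update(references)
        return cls(
            terms={b: list(covariates) for b in BLOCKS},
            references=refs,
            spline_bases=dict(spline_bases or {}),
        )

    def with_term(self, term: str) -> "DesignSpec":
        """A copy with ``term`` appended to every block (forward selection)."""
        return DesignSpec(
            terms={b: self.terms[b] + [term] for b in BLOCKS},
            references=dict(self.references),
            spline_bases=dict(self.spline_bases),
        )

    def all_terms(self) -> list[str]:
        seen: list[str] = []
        for b in BLOCKS:
            for t in self.terms[b]:
                if t not in seen:
                    seen.append(t)
        return seen


@dataclasses.dataclass
class DesignMatrices:
    """Evaluated designs for all five blocks plus the fitted codings."""

    X: dict[str, np.ndarray]                 # block -> (n, p_block)
    columns: dict[str, list[str]]            # block -> column names
    penalties: dict[str, np.ndarray | None]  # block -> full-size penalty or None
    splines: dict[str, SplineBasis]          # variable -> fitted basis
    levels: dict[str, list[str]]             # factor -> fitted level order
    spec: DesignSpec

    @property
    def n(self) -> int:
        return self.X["mu1"].shape[0]

    def block_sizes(self) -> dict[str, int]:
        return {b: self.X[b].shape[1] for b in BLOCKS}

    def spline_slice(self, block: str, variable: str) -> slice:
        cols = self.columns[block]
        idx = [i for i, c in enumerate(cols) if c.startswith(f"s({variable}).")]
        if not idx:
            raise KeyError(f"no smooth for {variable!r} in block {block!r}")
        return slice(idx[0], idx[-1] + 1)


def _encode_factor(
    col: pd.Series, name: str, reference: str, levels: list[str] | None
) -> tuple[np.ndarray, list[str], list[str]]:
    vals = col.astype(str)
    if levels is None:
        observed = list(pd.unique(vals))
        if reference not in observed:
            raise CodingError(
                f"reference level {reference!r} of {name!r} not observed "
                f"(levels: {observed})"
            )
        levels = [reference] + sorted(l for l in observed if l != reference)
    unseen = set(vals) - set(levels)
    if unseen:
        raise CodingError(f"unseen level(s) {sorted(unseen)} in factor {name!r}")
    cols = []
    names = []
    for level in levels[1:]:
        cols.append((vals == level).to_numpy(dtype=float))
        names.append(f"{name}[{level}]")
    return np.column_stack(cols) if cols else np.empty((len(vals), 0)), names, levels


def build_design(
    spec: DesignSpec,
    data: pd.DataFrame,
    fitted: DesignMatrices | None = None,
) -> DesignMatrices:
    """Expand a :class:`DesignSpec` against a data frame.

    Passing ``fitted`` reuses its factor level orders and spline bases, so the
    new matrix is comparable (prediction mode); unseen levels then raise
    :class:`CodingError`.
    """
    splines: dict[str, SplineBasis] = dict(fitted.splines) if fitted else {}
    levels: dict[str, list[str]] = dict(fitted.levels) if fitted else {}
    X: dict[str, np.ndarray] = {}
    columns: dict[str, list[str]] = {}
    penalties: dict[str, np.ndarray | None] = {}
    n = len(data)

    for block in BLOCKS:
        mats = [np.ones((n, 1))]
        names = ["Intercept"]
        pen_blocks: list[tuple[int, np.ndarray]] = []  # (start col, penalty)
        for term in spec.terms[block]:
            if is_spline_term(term):
                var = spline_variable(term)
                if var not in data.columns:
                    raise KeyError(f"smooth variable {var!r} not in data")
                if var not in splines:
                    splines[var] = build_spline_basis(
                        data[var].to_numpy(dtype=float),
                        variable=var,
                        n_bases=spec.spline_bases.get(var, 5),
                    )
                basis = splines[var]
                Xs = basis.evaluate(
                    data[var].to_numpy(dtype=float),
                    warn_extrapolation=fitted is not None,
                )
                pen_blocks.append((sum(m.shape[1] for m in mats), basis.penalty))
                mats.append(Xs)
                names.extend(basis.column_names())
            elif term not in data.columns:
                raise KeyError(f"term {term!r} not in data")
            elif pd.api.types.is_numeric_dtype(data[term]):
                mats.append(data[term].to_numpy(dtype=float)[:, None])
                names.append(term)
            else:
                ref = spec.references.get(term)
                if ref is None:
                    raise CodingError(f"no reference level configured for {term!r}")
                enc, enc_names, lev = _encode_factor(
                    data[term], term, ref, levels.get(term)
                )
                levels[term] = lev
                mats.append(enc)
                names.extend(enc_names)
        Xb = np.hstack(mats)
        X[block] = Xb
        columns[block] = names
        if pen_blocks:
            P = np.zeros((Xb.shape[1], Xb.shape[1]))
            for start, pen in pen_blocks:
                d = pen.shape[0]
                P[start : start + d, start : start + d] = pen
            penalties[block] = P
        else:
            penalties[block] = None

    return DesignMatrices(
        X=X, columns=columns, penalties=penalties,
        splines=splines, levels=levels, spec=spec,
    )
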