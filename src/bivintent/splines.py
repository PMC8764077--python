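"""Low-rank thin-plate regression spline basis for one covariate.

The smooth term for age uses the standard low-rank eigen-construction: the
full thin-plate radial basis over the (possibly thinned) unique covariate
values is eigendecomposed, the leading-magnitude eigenvectors are retained,
the polynomial-null-space constraint is absorbed, and the whole smooth is
centred so its columns are orthogonal to the intercept.  With `n_bases = 5`
the constrained smooth contributes 4 design columns (3 penalized "wiggly"
directions plus the unpenalized linear term).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np


class ExtrapolationWarning(UserWarning):
    pass


def _eta(r: np.ndarray) -> np.ndarray:
    # 1-d thin-plate (m=2) radial basis; the 1/12 constant is absorbed into
    # the smoothing parameter
    return r**3 / 12.0


@dataclasses.dataclass
class SplineBasis:
    """Fitted thin-plate regression spline term.

    ``penalty`` is the symmetric PSD matrix on the final (constrained,
    centred, rescaled) coefficient vector; the last column is the linear
    null-space direction and carries zero penalty.
    """

    variable: str
    n_bases: int
    knots: np.ndarray           # thinned unique covariate values
    projector: np.ndarray       # (n_knots, n_wiggly): U_k @ Z, post-constraint
    col_scale: np.ndarray       # per-column rescaling applied for conditioning
    col_center: np.ndarray      # fitting-sample column means (sum-to-zero)
    penalty: np.ndarray         # (dim, dim)
    x_range: tuple[float, float]
    x_center: float

    @property
    def dim(self) -> int:
        return self.projector.shape[1] + 1

    def evaluate(self, x: np.ndarray, warn_extrapolation: bool = True) -> np.ndarray:
        """Design columns of the smooth at new covariate values."""
        x = np.asarray(x, dtype=float)
        lo, hi = self.x_range
        if warn_extrapolation and ((x < lo) | (x > hi)).any():
            warnings.warn(
                f"evaluating {self.variable!r} smooth outside the fitted "
                f"range [{lo:g}, {hi:g}]", ExtrapolationWarning,
            )
        E = _eta(np.abs(x[:, None] - self.knots[None, :]))
        wiggly = E @ self.projector
        linear = (x - self.x_center)[:, None]
        X = np.hstack([wiggly, linear]) / self.col_scale
        return X - self.col_center

    def column_names(self) -> list[str]:
        return [f"s({self.variable}).{i+1}" for i in range(self.dim)]


def build_spline_basis(
    x: np.ndarray, variable: str = "age", n_bases: int = 5, max_knots: int = 100
) -> SplineBasis:
    """Construct the low-rank thin-plate basis from observed covariate values.

    ``n_bases`` counts basis functions before constraint absorption (the
    published default is 5); two are absorbed by the polynomial-null-space
    constraint and one by centring, leaving ``n_bases - 1`` design columns.
    """
    x = np.asarray(x, dtype=float)
    uniq = np.unique(x)
    if uniq.size < n_bases:
        raise ValueError(
            f"{variable!r} has {uniq.size} distinct values; need >= {n_bases}"
        )
    if uniq.size > max_knots:
        knots = np.unique(np.quantile(uniq, np.linspace(0, 1, max_knots)))
    else:
        knots = uniq

    E = _eta(np.abs(knots[:, None] - knots[None, :]))
    T = np.column_stack([np.ones_like(knots), knots])
    evals, evecs = np.linalg.eigh(E)
    order = np.argsort(np.abs(evals))[::-1][:n_bases]
    U_k = evecs[:, order]
    D_k = evals[order]

    # absorb the null-space constraint T' delta = 0 (delta = U_k d, d = Z c)
    M = T.T @ U_k                        # (2, n_bases)
    _, _, Vt = np.linalg.svd(M)
    Z = Vt[2:].T                         # (n_bases, n_bases - 2)
    proj = U_k @ Z
    pen_w = Z.T @ np.diag(D_k) @ Z       # penalty on wiggly coefficients
    pen_w = (pen_w + pen_w.T) / 2.0

    # rescale columns to unit sd on the fitting sample for conditioning
    E_x = _eta(np.abs(x[:, None] - knots[None, :]))
    wiggly = E_x @ proj
    linear = (x - x.mean())[:, None]
    raw = np.hstack([wiggly, linear])
    col_scale = raw.std(axis=0, ddof=0)
    col_scale[col_scale == 0] = 1.0
    # dividing column j by s_j multiplies its coefficient by s_j, so the
    # penalty transforms by the inverse scales
    S_inv = np.diag(1.0 / col_scale[:-1])
    pen_scaled = S_inv @ pen_w @ S_inv

    dim = proj.shape[1] + 1
    penalty = np.zeros((dim, dim))
    penalty[:-1, :-1] = pen_scaled

    basis = SplineBasis(
        variable=variable,
        n_bases=n_bases,
        knots=knots,
        projector=proj,
        col_scale=col_scale,
        col_center=np.zeros(dim),
        penalty=penalty,
        x_range=(float(x.min()), float(x.max())),
        x_center=float(x.mean()),
    )
    X0 = basis.evaluate(x, warn_extrapolation=False)
    basis.col_center = X0.mean(axis=0)
    return basis
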