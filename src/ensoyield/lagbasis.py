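"""Exposure histories and the exposure x lag tensor-product (cross-basis) design.

The cross-basis encodes a bivariate exposure-lag-response surface: a B-spline
basis over exposure intensity is crossed with a B-spline basis over lag, and
each observation's row is the lag-summed outer product of the two bases
evaluated along its exposure history.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "BasisSpec",
    "CrossBasis",
    "log_knots",
    "bspline_basis",
    "build_exposure_history",
    "build_crossbasis",
    "default_exposure_spec",
    "quadratic_exposure_spec",
    "default_lag_spec",
    "read_enso_csv",
    "write_enso_csv",
]


@dataclass(frozen=True)
class BasisSpec:
    """Specification of a univariate B-spline basis.

    Dimension is ``len(internal_knots) + degree`` without an intercept and one
    more with it (the full Cox-de Boor basis, which forms a partition of unity
    on the boundary interval).
    """

    degree: int = 3
    internal_knots: tuple[float, ...] = ()
    boundary: tuple[float, float] = (0.0, 1.0)
    include_intercept: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.boundary
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if not lo < hi:
            raise ValueError("boundary must satisfy lo < hi")
        knots = tuple(float(k) for k in self.internal_knots)
        if any(not lo < k < hi for k in knots):
            raise ValueError("internal knots must lie strictly inside the boundary")
        if list(knots) != sorted(knots):
            raise ValueError("internal knots must be sorted")
        object.__setattr__(self, "internal_knots", knots)

    @property
    def dim(self) -> int:
        return len(self.internal_knots) + self.degree + (1 if self.include_intercept else 0)

    @property
    def full_knot_vector(self) -> np.ndarray:
        lo, hi = self.boundary
        return np.concatenate(
            [np.repeat(lo, self.degree + 1), self.internal_knots, np.repeat(hi, self.degree + 1)]
        )

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "internal_knots": list(self.internal_knots),
            "boundary": list(self.boundary),
            "include_intercept": self.include_intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSpec":
        return cls(
            degree=int(d["degree"]),
            internal_knots=tuple(d["internal_knots"]),
            boundary=tuple(d["boundary"]),
            include_intercept=bool(d["include_intercept"]),
        )


def log_knots(L: int, nk: int = 3) -> np.ndarray:
    """Knot positions equally spaced on the log-lag scale: ``L**(i/(nk+1))``.

    Parameters
    ----------
    L : maximum lag (months); must be >= 2.
    nk : number of internal knots.
    """
    if L < 2:
        raise ValueError("log_knots requires L >= 2")
    if nk < 1:
        raise ValueError("log_knots requires nk >= 1")
    i = np.arange(1, nk + 1)
    return np.power(float(L), i / (nk + 1))


def bspline_basis(x, spec: BasisSpec) -> np.ndarray:
    """Evaluate the B-spline basis at ``x`` (no extrapolation allowed).

    Returns an ``(len(x), spec.dim)`` matrix.  With the intercept the rows sum
    to one on the boundary interval; without it the first basis function is
    dropped (as in R's ``bs``) so the column space excludes the constant.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    lo, hi = spec.boundary
    if x.size and (x.min() < lo or x.max() > hi):
        bad = x[(x < lo) | (x > hi)][0]
        raise ValueError(f"value {bad!r} outside basis boundary [{lo}, {hi}]")
    t = spec.full_knot_vector
    # exposure histories repeat heavily across estates/lags: evaluate each
    # distinct value once and broadcast back
    ux, inv = np.unique(x, return_inverse=True)
    B = BSpline.design_matrix(ux, t, spec.degree, extrapolate=False).toarray()[inv]
    if not spec.include_intercept:
        B = B[:, 1:]
    return B


def _check_contiguous(series: pd.Series) -> pd.Series:
    if not isinstance(series.index, pd.PeriodIndex):
        raise TypeError("exposure series must be indexed by a monthly PeriodIndex")
    series = series.sort_index()
    idx = series.index
    if len(idx) > 1:
        steps = np.diff(idx.asi8)
        if not np.all(steps == 1):
            gap_pos = int(np.argmax(steps != 1))
            raise ValueError(f"exposure series has a calendar gap after {idx[gap_pos]}")
    if series.isna().any():
        raise ValueError("exposure series contains missing values")
    return series


def build_exposure_history(series: pd.Series, periods, L: int) -> np.ndarray:
    """Matrix ``Q`` with ``Q[i, l]`` = series value ``l`` months before period i.

    ``series`` must be a gap-free monthly :class:`pandas.Series`; ``periods``
    is the per-observation vector of calendar months.  Raises if any required
    history month is missing, naming the earliest such month.
    """
    series = _check_contiguous(series)
    periods = pd.PeriodIndex(periods, freq="M")
    first = series.index[0]
    pos = periods.asi8 - first.ordinal
    if (pos - L).min() < 0:
        earliest = periods[int(np.argmin(pos))] - L
        raise ValueError(f"exposure history incomplete: series starts after {earliest}")
    if pos.max() >= len(series):
        raise ValueError(f"exposure series ends before {periods.max()}")
    values = series.to_numpy()
    lags = np.arange(L + 1)
    return values[pos[:, None] - lags[None, :]]


def default_exposure_spec(Q: np.ndarray, pad: tuple[float, float] | None = (-1.5, 2.5)) -> BasisSpec:
    """Default exposure-dimension spec: cubic, knots at the exposure quartiles,
    no intercept.

    The boundary is the observed exposure range, optionally widened to cover
    the standard reporting contrasts (x = -1 and x = +2) so association curves
    evaluated there never extrapolate.
    """
    q = np.asarray(Q, dtype=float).ravel()
    lo, hi = float(q.min()), float(q.max())
    if pad is not None:
        lo, hi = min(lo, pad[0]), max(hi, pad[1])
    knots = tuple(np.quantile(q, [0.25, 0.50, 0.75]))
    # collapse duplicate/degenerate knots (e.g. heavily tied exposures)
    knots = tuple(sorted({k for k in knots if lo < k < hi}))
    return BasisSpec(degree=3, internal_knots=knots, boundary=(lo, hi), include_intercept=False)


def quadratic_exposure_spec(
    Q: np.ndarray, knot: float = 0.0, pad: tuple[float, float] | None = (-2.6, 3.2)
) -> BasisSpec:
    """Degree-2 exposure spec with an internal knot pinned at the reference.

    A quadratic B-spline is C1 at its knots, so this basis can represent an
    exposure response whose curvature changes discontinuously at the reference
    value (e.g. different cool-phase and warm-phase quadratics) exactly —
    useful for recovery studies against piecewise-quadratic ground truths.
    """
    q = np.asarray(Q, dtype=float).ravel()
    lo, hi = float(q.min()), float(q.max())
    if pad is not None:
        lo, hi = min(lo, pad[0]), max(hi, pad[1])
    knots = set(np.quantile(q, [0.25, 0.75])) | {float(knot)}
    knots = tuple(sorted(k for k in knots if lo < k < hi))
    return BasisSpec(degree=2, internal_knots=knots, boundary=(lo, hi), include_intercept=False)


def default_lag_spec(L: int, nk: int = 3) -> BasisSpec:
    """Default lag-dimension spec: cubic with intercept, log-scale knots.

    The basis is only ever evaluated at the L+1 integer lags, so the knot
    count is capped at ``L - degree`` to keep the lag design full rank.
    """
    degree = 3
    nk_eff = min(nk, max(L - degree, 0))
    knots = tuple(log_knots(L, nk_eff)) if nk_eff >= 1 else ()
    return BasisSpec(
        degree=degree,
        internal_knots=knots,
        boundary=(0.0, float(L)),
        include_intercept=True,
    )


@dataclass
class CrossBasis:
    """Tensor-product design block for a distributed-lag non-linear model.

    ``W`` has one row per observation and ``dim_x * dim_l`` columns, ordered
    exposure-major: column ``j*dim_l + k`` pairs exposure basis function ``j``
    with lag basis function ``k``, so contrast vectors are Kronecker products
    ``kron(b_x, c_l)``.
    """

    W: np.ndarray
    x_spec: BasisSpec
    l_spec: BasisSpec
    L: int
    x0: float = 0.0
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.column_names:
            self.column_names = [
                f"cb_x{j}_l{k}" for j in range(self.x_spec.dim) for k in range(self.l_spec.dim)
            ]

    @property
    def dim(self) -> int:
        return self.x_spec.dim * self.l_spec.dim

    def exposure_basis(self, x) -> np.ndarray:
        return bspline_basis(x, self.x_spec)

    def lag_basis(self, l) -> np.ndarray:
        return bspline_basis(l, self.l_spec)

    def lag_sum(self) -> np.ndarray:
        """Sum of the lag basis over the integer lags 0..L."""
        return self.lag_basis(np.arange(self.L + 1)).sum(axis=0)

    def specs_json(self) -> str:
        return json.dumps(
            {
                "x_spec": self.x_spec.to_dict(),
                "l_spec": self.l_spec.to_dict(),
                "L": self.L,
                "x0": self.x0,
            },
            indent=2,
        )


def build_crossbasis(
    Q: np.ndarray,
    x_spec: BasisSpec | None = None,
    l_spec: BasisSpec | None = None,
    x0: float = 0.0,
) -> CrossBasis:
    """Build the cross-basis matrix from an exposure-history matrix ``Q``.

    Row ``i`` of ``W`` is ``vec( sum_l  b_x(Q[i, l]) c_l(l)^T )`` — the
    lag-summed outer product of the exposure basis evaluated at each lagged
    exposure with the lag basis evaluated at that lag.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2:
        raise ValueError("Q must be a 2-d (observations x lags) matrix")
    n, ncol = Q.shape
    L = ncol - 1
    if x_spec is None:
        x_spec = default_exposure_spec(Q)
    if l_spec is None:
        l_spec = default_lag_spec(L)
    Bx = bspline_basis(Q.ravel(), x_spec).reshape(n, L + 1, x_spec.dim)
    Cl = bspline_basis(np.arange(L + 1, dtype=float), l_spec)
    W = np.einsum("nlx,ly->nxy", Bx, Cl).reshape(n, x_spec.dim * l_spec.dim)
    if x_spec.dim * l_spec.dim > n:
        warnings.warn(
            f"cross-basis dimension {x_spec.dim * l_spec.dim} exceeds n={n}",
            stacklevel=2,
        )
    return CrossBasis(W=W, x_spec=x_spec, l_spec=l_spec, L=L, x0=x0)


def read_enso_csv(path, index_name: str | None = None) -> pd.Series:
    """Read a (year, month, index_name, value) CSV into a monthly series."""
    df = pd.read_csv(path)
    if index_name is not None:
        df = df[df["index_name"] == index_name]
    if df.empty:
        raise ValueError(f"no rows for index {index_name!r} in {path}")
    idx = pd.PeriodIndex(
        [pd.Period(year=y, month=m, freq="M") for y, m in zip(df["year"], df["month"])], freq="M"
    )
    s = pd.Series(df["value"].to_numpy(dtype=float), index=idx, name=df["index_name"].iloc[0])
    return _check_contiguous(s)


def write_enso_csv(series: pd.Series, path, index_name: str = "enso") -> None:
    idx = pd.PeriodIndex(series.index, freq="M")
    out = pd.DataFrame(
        {
            "year": idx.year,
            "month": idx.month,
            "index_name": index_name,
            "value": series.to_numpy(dtype=float),
        }
    )
    out.to_csv(path, index=False)
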