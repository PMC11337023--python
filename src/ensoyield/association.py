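"""Cumulative and lag-specific exposure-response associations with
delta-method confidence intervals relative to the reference exposure.

Contrasts are linear in the cross-basis coefficients: the cumulative contrast
at exposure ``x`` is ``kron(b_x(x) - b_x(x0), sum_l c_l(l))`` and its variance
follows from the fitted coefficient covariance, so the cumulative effect is
exactly the sum of the integer-lag effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lagbasis import CrossBasis
from .modelfit import FitResult

__all__ = [
    "AssociationCurve",
    "LagSurface",
    "cumulative_association",
    "lag_association",
    "association_table",
    "contour_matrix",
    "monthly_equivalent",
    "percent_of_mean",
    "format_estimate",
]

Z95 = 1.959963984540054  # standard normal 97.5 % quantile


@dataclass
class AssociationCurve:
    x: np.ndarray
    effect: np.ndarray
    se: np.ndarray
    x0: float
    L: int

    @property
    def lo(self) -> np.ndarray:
        return self.effect - Z95 * self.se

    @property
    def hi(self) -> np.ndarray:
        return self.effect + Z95 * self.se

    @property
    def lag_label(self) -> str:
        return f"0-{self.L}"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.x, "effect": self.effect, "se": self.se, "lo": self.lo, "hi": self.hi}
        )

    def at(self, x: float) -> tuple[float, float]:
        """Point estimate and SE at a grid value (must be on the grid)."""
        i = int(np.argmin(np.abs(self.x - x)))
        if not np.isclose(self.x[i], x):
            raise KeyError(f"{x} not on the evaluated grid")
        return float(self.effect[i]), float(self.se[i])


@dataclass
class LagSurface:
    x: np.ndarray
    l: np.ndarray
    effect: np.ndarray  # (len(x), len(l))
    se: np.ndarray
    x0: float

    def to_frame(self) -> pd.DataFrame:
        xx, ll = np.meshgrid(self.x, self.l, indexing="ij")
        return pd.DataFrame(
            {
                "x": xx.ravel(),
                "lag": ll.ravel(),
                "effect": self.effect.ravel(),
                "se": self.se.ravel(),
            }
        )


def _cumulative_contrasts(cb: CrossBasis, x, x0: float) -> np.ndarray:
    Bx = cb.exposure_basis(x) - cb.exposure_basis([x0])
    csum = cb.lag_sum()
    return np.kron(Bx, csum[None, :]).reshape(len(np.atleast_1d(x)), -1)


def cumulative_association(
    fit: FitResult, cb: CrossBasis, x_values, x0: float | None = None
) -> AssociationCurve:
    """Cumulative (lag-summed) effect of each exposure value relative to the
    reference, with delta-method standard errors."""
    x0 = cb.x0 if x0 is None else x0
    x = np.atleast_1d(np.asarray(x_values, dtype=float))
    Z = _cumulative_contrasts(cb, x, x0)
    beta, V = fit.cb_beta, fit.cb_cov
    effect = Z @ beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Z, V, Z), 0.0))
    return AssociationCurve(x=x, effect=effect, se=se, x0=x0, L=cb.L)


def lag_association(
    fit: FitResult, cb: CrossBasis, x: float, l: float, x0: float | None = None
) -> tuple[float, float]:
    """Effect and SE of exposure ``x`` (vs reference) at a single lag."""
    x0 = cb.x0 if x0 is None else x0
    if not 0 <= l <= cb.L:
        raise ValueError(f"lag {l} outside 0..{cb.L}")
    if float(l) != int(l):
        warnings.warn("non-integer lag requested; basis is continuous in lag", stacklevel=2)
    bx = cb.exposure_basis([x])[0] - cb.exposure_basis([x0])[0]
    cl = cb.lag_basis([float(l)])[0]
    z = np.kron(bx, cl)
    effect = float(z @ fit.cb_beta)
    se = float(np.sqrt(max(z @ fit.cb_cov @ z, 0.0)))
    return effect, se


def monthly_equivalent(cumulative: float, L: int) -> float:
    """Convert a cumulative effect over lags 0..L to a per-month equivalent."""
    return cumulative / (L + 1)


def percent_of_mean(monthly: float, mean: float) -> int:
    """Magnitude of a monthly effect as an integer percent of the outcome mean."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    return int(round(abs(monthly) / mean * 100))


def format_estimate(effect: float, lo: float, hi: float, digits: int = 2) -> str:
    return f"{effect:.{digits}f} ({lo:.{digits}f}, {hi:.{digits}f})"


def association_table(
    fit: FitResult,
    cb: CrossBasis,
    x_values=(-1.0, 2.0),
    index_name: str = "enso",
    outcome: str = "ffb_yield",
) -> pd.DataFrame:
    """Cumulative-contrast summary rows (one per exposure value), including
    the per-month equivalent of the cumulative effect."""
    curve = cumulative_association(fit, cb, x_values)
    rows = []
    for xi, eff, lo, hi in zip(curve.x, curve.effect, curve.lo, curve.hi):
        rows.append(
            {
                "index": index_name,
                "outcome": outcome,
                "lags": curve.lag_label,
                "x": xi,
                "effect": eff,
                "lo": lo,
                "hi": hi,
                "formatted": format_estimate(eff, lo, hi),
                "monthly_equivalent": monthly_equivalent(eff, cb.L),
            }
        )
    return pd.DataFrame(rows)


def contour_matrix(
    fit: FitResult,
    cb: CrossBasis,
    x_grid=None,
    l_grid=None,
    x0: float | None = None,
) -> LagSurface:
    """Dense exposure-by-lag effect surface for contour plotting."""
    x0 = cb.x0 if x0 is None else x0
    if x_grid is None:
        lo, hi = cb.x_spec.boundary
        x_grid = np.linspace(lo, hi, 60)
    if l_grid is None:
        l_grid = np.arange(cb.L + 1, dtype=float)
    x_grid = np.asarray(x_grid, dtype=float)
    l_grid = np.asarray(l_grid, dtype=float)
    Bx = cb.exposure_basis(x_grid) - cb.exposure_basis([x0])
    Cl = cb.lag_basis(l_grid)
    # z for cell (i,j) = kron(Bx[i], Cl[j]); evaluate all cells at once
    beta = fit.cb_beta.reshape(cb.x_spec.dim, cb.l_spec.dim)
    effect = Bx @ beta @ Cl.T
    V = fit.cb_cov
    nx, nl = len(x_grid), len(l_grid)
    se = np.empty((nx, nl))
    for j in range(nl):
        Z = np.kron(Bx, Cl[j][None, :]).reshape(nx, -1)
        se[:, j] = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Z, V, Z), 0.0))
    return LagSurface(x=x_grid, l=l_grid, effect=effect, se=se, x0=x0)
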