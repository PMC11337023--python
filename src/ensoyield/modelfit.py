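"""Outcome model fitting: cross-basis + selected covariates + calendar-month
and state fixed effects, by ordinary least squares; AIC-based lag-window
selection; and a Gaussian random-intercept robustness fit.

The additive model is fully parametric — all nonlinearity lives in the
cross-basis block — so the Gaussian AIC is exact and model-based covariance
matrices feed straight into delta-method contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .lagbasis import BasisSpec, CrossBasis, build_crossbasis, build_exposure_history, default_lag_spec

__all__ = [
    "ModelSpec",
    "FitResult",
    "build_design",
    "fit_fixed",
    "select_max_lag",
    "fit_random_intercept",
    "wald_crossbasis",
]


@dataclass(frozen=True)
class ModelSpec:
    outcome: str = "ffb_yield"
    covariates: tuple[str, ...] = ()
    month_fe: bool = True
    state_fe: bool = True
    drop_month: int = 1
    drop_state: str | None = None  # None -> first level in sorted order


@dataclass
class FitResult:
    params: pd.Series
    cov: pd.DataFrame
    sigma2: float
    aic: float
    n: int
    p: int
    cb_names: list[str]
    rss: float
    sigma2_b: float | None = None
    converged: bool = True
    method: str = "ols"

    def __post_init__(self) -> None:
        V = self.cov.to_numpy()
        if not np.allclose(V, V.T, atol=1e-8 * (1 + np.abs(V).max())):
            raise ValueError("covariance matrix is not symmetric")

    @property
    def cb_beta(self) -> np.ndarray:
        return self.params[self.cb_names].to_numpy()

    @property
    def cb_cov(self) -> np.ndarray:
        return self.cov.loc[self.cb_names, self.cb_names].to_numpy()


def build_design(
    df: pd.DataFrame, spec: ModelSpec, cb: CrossBasis | None
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the fixed-effects design: intercept, cross-basis block,
    month-of-year and state dummies (reference levels dropped), covariates.

    ``cb=None`` fits the covariate-only model.  Rows with a missing outcome
    are dropped (with the matching cross-basis rows) rather than imputed.
    """
    if cb is not None and len(df) != cb.W.shape[0]:
        raise ValueError("panel and cross-basis row counts differ")
    y = pd.Series(df[spec.outcome].to_numpy(dtype=float), index=df.index, name=spec.outcome)
    keep = y.notna().to_numpy()
    df = df.loc[keep]
    y = y.loc[keep]
    blocks = [pd.DataFrame({"const": np.ones(len(df))}, index=df.index)]
    if cb is not None:
        blocks.append(pd.DataFrame(cb.W[keep], columns=cb.column_names, index=df.index))
    if spec.month_fe:
        months = pd.PeriodIndex(df["period"], freq="M").month
        md = pd.get_dummies(pd.Categorical(months, categories=range(1, 13)), prefix="month", dtype=float)
        md.index = df.index
        md = md.drop(columns=[f"month_{spec.drop_month}"])
        blocks.append(md)
    if spec.state_fe:
        sd = pd.get_dummies(df["state"], prefix="state", dtype=float)
        drop = f"state_{spec.drop_state}" if spec.drop_state else sd.columns[0]
        sd = sd.drop(columns=[drop])
        blocks.append(sd)
    for col in spec.covariates:
        v = df[col]
        if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
            raise ValueError(f"covariate {col!r} must be numeric (expand categoricals upstream)")
        blocks.append(v.astype(float).to_frame(col))
    X = pd.concat(blocks, axis=1)
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValueError(f"missing values in design columns {bad}")
    return X, y


def gaussian_aic(rss: float, n: int, p: int) -> float:
    """AIC of the Gaussian linear model with p mean parameters (+1 variance)."""
    rss = max(rss, np.finfo(float).tiny)
    return n * np.log(rss / n) + 2 * (p + 1) + n * (1 + np.log(2 * np.pi))


def fit_fixed(df: pd.DataFrame, spec: ModelSpec, cb: CrossBasis) -> FitResult:
    """Ordinary-least-squares fit of the additive model."""
    X, y = build_design(df, spec, cb)
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy()
    n, p = Xv.shape
    Q, R, piv = scipy.linalg.qr(Xv, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    tol = d.max() * max(n, p) * np.finfo(float).eps
    rank = int((d > tol).sum())
    if rank < p:
        aliased = [names[j] for j in piv[rank:]]
        raise ValueError(f"design is rank deficient; aliased columns: {aliased}")
    beta_piv = scipy.linalg.solve_triangular(R, Q.T @ yv)
    beta = np.empty(p)
    beta[piv] = beta_piv
    resid = yv - Xv @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - p)
    Rinv = scipy.linalg.solve_triangular(R, np.eye(p))
    V_piv = sigma2 * (Rinv @ Rinv.T)
    V = np.empty((p, p))
    V[np.ix_(piv, piv)] = V_piv
    cb_names = [] if cb is None else [c for c in names if c in set(cb.column_names)]
    return FitResult(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(V, index=names, columns=names),
        sigma2=sigma2,
        aic=gaussian_aic(rss, n, p),
        n=n,
        p=p,
        cb_names=cb_names,
        rss=rss,
    )


def select_max_lag(
    df: pd.DataFrame,
    spec: ModelSpec,
    enso: pd.Series,
    candidates: list[int],
    x_spec: BasisSpec | None = None,
    lag_spec_factory=default_lag_spec,
    x0: float = 0.0,
):
    """Refit the model at each candidate maximum lag; return the AIC-minimal
    lag (ties broken toward fewer lags), the AIC table, and the winning fit.

    Returns ``(L_star, table, fit, cb)``.
    """
    if not candidates:
        raise ValueError("need at least one candidate lag")
    periods = pd.PeriodIndex(df["period"], freq="M")
    rows, fits = [], {}
    for L in sorted(candidates):
        Q = build_exposure_history(enso, periods, L)
        cb = build_crossbasis(Q, x_spec=x_spec, l_spec=lag_spec_factory(L), x0=x0)
        fit = fit_fixed(df, spec, cb)
        rows.append({"L": L, "aic": fit.aic, "p": fit.p})
        fits[L] = (fit, cb)
    table = pd.DataFrame(rows)
    best = int(table.loc[table["aic"].idxmin(), "L"])  # idxmin takes first == smallest L on ties
    fit, cb = fits[best]
    return best, table, fit, cb


def wald_crossbasis(fit: FitResult) -> tuple[float, float]:
    """Wald chi-square test that the whole cross-basis block is zero."""
    beta = fit.cb_beta
    V = fit.cb_cov
    stat = float(beta @ np.linalg.solve(V, beta))
    dof = len(beta)
    return stat, float(stats.chi2.sf(stat, dof))


def fit_random_intercept(
    df: pd.DataFrame,
    spec: ModelSpec,
    cb: CrossBasis,
    group_col: str = "estate_id",
    reml: bool = True,
    maxiter: int = 200,
) -> FitResult:
    """Gaussian random-intercept model (identity-link PQL is exactly the
    linear mixed model), fitted by REML via statsmodels.

    Returns the fixed-effect estimates with their model-based covariance plus
    the residual and between-group variance components.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    X, y = build_design(df, spec, cb)
    groups = df.loc[X.index, group_col]
    counts = groups.value_counts()
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 groups with >= 2 observations each")
    names = list(X.columns)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y.to_numpy(), X.to_numpy(dtype=float), groups=groups.to_numpy())
        res = model.fit(reml=reml, maxiter=maxiter)
        if not res.converged:
            res = model.fit(reml=reml, maxiter=maxiter, method="cg")
    # a between-group variance at/near the zero boundary is a legitimate
    # degenerate fit, not an optimizer failure
    at_boundary = float(np.asarray(res.cov_re)[0, 0]) < 1e-2 * float(res.scale)
    if not res.converged and not at_boundary:
        raise RuntimeError(f"random-intercept fit did not converge in {maxiter} iterations")
    k = len(names)
    params = pd.Series(np.asarray(res.fe_params), index=names)
    V = pd.DataFrame(np.asarray(res.cov_params())[:k, :k], index=names, columns=names)
    sigma2 = float(res.scale)
    sigma2_b = float(np.asarray(res.cov_re)[0, 0])
    resid = y.to_numpy() - X.to_numpy(dtype=float) @ params.to_numpy()
    cb_names = [] if cb is None else [c for c in names if c in set(cb.column_names)]
    return FitResult(
        params=params,
        cov=V,
        sigma2=sigma2,
        aic=float(res.aic) if np.isfinite(res.aic) else np.nan,
        n=len(y),
        p=k,
        cb_names=cb_names,
        rss=float(resid @ resid),
        sigma2_b=sigma2_b,
        converged=bool(res.converged),
        method="reml_random_intercept",
    )
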