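"""LASSO covariate screening with a cross-validated penalty.

The penalized fit minimises ``(1/2n)||y - b0 - X b||^2 + lambda ||b||_1`` by
cyclic coordinate descent on a precomputed Gram matrix (candidate sets here
are small, so the Gram formulation makes the full path essentially free).
The exposure cross-basis is never part of the candidate set — screening only
ever touches the adjustment covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CovariateMatrix",
    "SelectionResult",
    "build_covariate_matrix",
    "soft_threshold",
    "lasso_fit",
    "lambda_max",
    "lambda_grid",
    "cv_select",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass
class CovariateMatrix:
    """Standardized candidate design plus the raw numeric frame it came from.

    ``X`` holds mean-0/SD-1 columns for the penalized fit; ``frame`` keeps the
    raw (unstandardized) columns keyed by the same names for downstream
    unpenalized modelling.
    """

    X: np.ndarray
    columns: list[str]
    sources: list[str]
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.columns):
            raise ValueError("column metadata does not match design width")
        if np.isnan(self.X).any():
            raise ValueError("covariate matrix contains missing entries")


def build_covariate_matrix(
    df: pd.DataFrame,
    continuous: list[str] = (),
    categorical: list[str] = (),
) -> CovariateMatrix:
    """Expand categoricals to indicator columns, standardize everything.

    Missingness must already be encoded as categories upstream; a continuous
    column containing NaN is an error.  Constant columns are dropped (they are
    unidentifiable under standardization).
    """
    pieces, names, sources = [], [], []
    for col in continuous:
        v = df[col].to_numpy(dtype=float)
        pieces.append(v[:, None])
        names.append(col)
        sources.append(col)
    for col in categorical:
        dummies = pd.get_dummies(df[col], prefix=col, dtype=float)
        pieces.append(dummies.to_numpy())
        names.extend(dummies.columns)
        sources.extend([col] * dummies.shape[1])
    raw = np.hstack(pieces) if pieces else np.empty((len(df), 0))
    if np.isnan(raw).any():
        bad = [n for n, col in zip(names, raw.T) if np.isnan(col).any()]
        raise ValueError(f"missing values in candidate covariates {bad}")
    frame = pd.DataFrame(raw, columns=names, index=df.index)
    mu = raw.mean(axis=0)
    sd = raw.std(axis=0)
    keep = sd > 0
    X = (raw[:, keep] - mu[keep]) / sd[keep]
    return CovariateMatrix(
        X=X,
        columns=[n for n, k in zip(names, keep) if k],
        sources=[s for s, k in zip(sources, keep) if k],
        frame=frame,
    )


def soft_threshold(z, t):
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def lasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    max_iter: int = 100_000,
    tol: float = 1e-12,
    beta_init: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Coordinate-descent LASSO; returns (unpenalized intercept, coefficients).

    Convergence is declared when the largest coefficient update in a full
    sweep falls below ``tol`` (on the standardized scale).
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    ybar = y.mean()
    xbar = X.mean(axis=0)
    yc = y - ybar
    Xc = X - xbar
    G = Xc.T @ Xc
    b = Xc.T @ yc
    diag = np.diag(G).copy()
    if np.any(diag == 0):
        raise ValueError("constant column in LASSO design")
    beta = np.zeros(p) if beta_init is None else beta_init.astype(float).copy()
    nlam = n * lam
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            rho = b[j] - G[j] @ beta + diag[j] * beta[j]
            new = soft_threshold(rho, nlam) / diag[j]
            d = abs(new - beta[j])
            if d > delta:
                delta = d
            beta[j] = new
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"coordinate descent did not converge in {max_iter} sweeps (last delta {delta:.3e})"
        )
    intercept = ybar - xbar @ beta
    return float(intercept), beta


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every coefficient is zero (KKT threshold)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    Xc = X - X.mean(axis=0)
    return float(np.abs(Xc.T @ (y - y.mean())).max() / n)


def lambda_grid(lmax: float, n_lambda: int = 100, ratio: float = 1e-4) -> np.ndarray:
    return np.geomspace(lmax, lmax * ratio, n_lambda)


@dataclass
class SelectionResult:
    lambda_min: float
    cv_curve: pd.DataFrame  # columns: lam, mean_cv_error, se
    selected: list[str]
    coefficients: pd.Series
    seed: int
    k_folds: int = 10
    warnings: list[str] = field(default_factory=list)


def cv_select(
    cov: CovariateMatrix,
    y: np.ndarray,
    k_folds: int = 10,
    grid: np.ndarray | None = None,
    seed: int = 0,
) -> SelectionResult:
    """K-fold cross-validation over the penalty path; the minimum-mean-error
    lambda is refit on the full data to define the selected set."""
    X = cov.X
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < k_folds:
        raise ValueError("need n >= k_folds")
    if grid is None:
        grid = lambda_grid(lambda_max(X, y))
    grid = np.sort(np.asarray(grid, dtype=float))[::-1]
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 97)))
    fold = rng.permutation(n) % k_folds
    warns = []
    errs = np.zeros((len(grid), k_folds))
    for f in range(k_folds):
        tr, te = fold != f, fold == f
        if np.std(y[te]) == 0:
            warns.append(f"fold {f} has constant outcome")
        beta = np.zeros(X.shape[1])
        for gi, lam in enumerate(grid):  # warm start down the path
            b0, beta = lasso_fit(X[tr], y[tr], lam, beta_init=beta, tol=1e-9)
            pred = b0 + X[te] @ beta
            errs[gi, f] = np.mean((y[te] - pred) ** 2)
    mean_err = errs.mean(axis=1)
    se = errs.std(axis=1, ddof=1) / np.sqrt(k_folds)
    best = int(np.argmin(mean_err))
    lam_min = float(grid[best])
    b0, beta = lasso_fit(X, y, lam_min, tol=1e-10)
    coefs = pd.Series(beta, index=cov.columns)
    selected = [c for c, v in coefs.items() if v != 0.0]
    curve = pd.DataFrame({"lam": grid, "mean_cv_error": mean_err, "se": se})
    return SelectionResult(
        lambda_min=lam_min,
        cv_curve=curve,
        selected=selected,
        coefficients=coefs,
        seed=seed,
        k_folds=k_folds,
        warnings=warns,
    )
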