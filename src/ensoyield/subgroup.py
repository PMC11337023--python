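"""Stratified refits by effect modifiers and two-sample z-tests of cumulative
associations, with group-count-dependent significance thresholds."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import Z95, cumulative_association

__all__ = [
    "ComparisonResult",
    "significance_threshold",
    "z_test_difference",
    "se_from_ci",
    "stratified_fit",
    "compare_to_reference",
]


def significance_threshold(n_groups: int) -> float:
    """Comparison-wise alpha by group count: 0.05, 0.025, 0.0125 for 2/3/5
    groups — i.e. 0.05 / (n_groups - 1), applied to other counts as well."""
    if n_groups < 2:
        raise ValueError("need at least 2 groups to compare")
    return 0.05 / (n_groups - 1)


def se_from_ci(lo: float, hi: float) -> float:
    """Back out a standard error from a reported 95 % CI: (hi - lo) / (2 * 1.96)."""
    if hi < lo:
        raise ValueError("upper bound below lower bound")
    return (hi - lo) / (2 * Z95)


@dataclass
class ComparisonResult:
    b1: float
    se1: float
    b2: float
    se2: float
    difference: float
    lo: float
    hi: float
    z: float
    p: float
    alpha: float
    significant: bool
    degenerate: bool = False


def z_test_difference(
    b1: float, se1: float, b2: float, se2: float, n_groups: int = 2
) -> ComparisonResult:
    """Two-sample z-test of a difference in cumulative association estimates.

    CI is ``(b1 - b2) +/- 1.96 * sqrt(se1^2 + se2^2)``; significance is judged
    against the group-count-dependent alpha.
    """
    if se1 < 0 or se2 < 0:
        raise ValueError("standard errors must be >= 0")
    alpha = significance_threshold(n_groups)
    diff = b1 - b2
    se = float(np.hypot(se1, se2))
    degenerate = se == 0.0
    if degenerate:
        if diff != 0.0:
            warnings.warn("zero SEs with unequal estimates: degenerate comparison", stacklevel=2)
        z = np.inf if diff > 0 else (-np.inf if diff < 0 else 0.0)
        p = 0.0 if diff != 0 else 1.0
    else:
        z = diff / se
        p = 2 * stats.norm.sf(abs(z))
    return ComparisonResult(
        b1=b1,
        se1=se1,
        b2=b2,
        se2=se2,
        difference=diff,
        lo=diff - Z95 * se,
        hi=diff + Z95 * se,
        z=float(z),
        p=float(p),
        alpha=alpha,
        significant=bool(p < alpha),
        degenerate=degenerate,
    )


def stratified_fit(
    df: pd.DataFrame,
    group_col: str,
    fit_fn,
    x_values,
    min_n: int = 500,
) -> dict:
    """Independent refits per stratum of ``group_col``.

    ``fit_fn(sub_df)`` must return ``(fit, cb)``; strata below ``min_n`` rows
    are skipped with a warning.  Returns an ordered mapping
    ``level -> {"curve": AssociationCurve, "n": int, "fit": fit, "cb": cb}``
    where every curve shares the exposure grid and reference.
    """
    levels = (
        list(df[group_col].cat.categories)
        if isinstance(df[group_col].dtype, pd.CategoricalDtype)
        else sorted(df[group_col].dropna().unique())
    )
    out = {}
    for level in levels:
        sub = df[df[group_col] == level]
        if len(sub) == 0:
            continue
        if len(sub) < min_n:
            warnings.warn(f"stratum {level!r} has n={len(sub)} < {min_n}; skipped", stacklevel=2)
            continue
        try:
            fit, cb = fit_fn(sub)
        except ValueError as err:  # e.g. model not identifiable in the stratum
            warnings.warn(f"stratum {level!r} not identifiable ({err}); skipped", stacklevel=2)
            continue
        curve = cumulative_association(fit, cb, x_values)
        out[level] = {"curve": curve, "n": len(sub), "fit": fit, "cb": cb}
    return out


def compare_to_reference(strata: dict, x: float) -> pd.DataFrame:
    """Each-vs-first-level z-tests of the cumulative effect at exposure x."""
    levels = list(strata)
    if len(levels) < 2:
        raise ValueError("need at least 2 fitted strata")
    n_groups = len(levels)
    ref = levels[0]
    b_ref, se_ref = strata[ref]["curve"].at(x)
    rows = []
    for level in levels[1:]:
        b, se = strata[level]["curve"].at(x)
        cmp = z_test_difference(b, se, b_ref, se_ref, n_groups=n_groups)
        rows.append(
            {
                "pair": f"{level} vs {ref}",
                "x": x,
                "effect": b,
                "effect_ref": b_ref,
                "difference": cmp.difference,
                "lo": cmp.lo,
                "hi": cmp.hi,
                "p": cmp.p,
                "alpha": cmp.alpha,
                "significant": cmp.significant,
            }
        )
    return pd.DataFrame(rows)
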