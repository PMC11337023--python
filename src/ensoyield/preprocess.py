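"""Outcome construction, exclusion filters, missing-category coding,
descriptives, rolling weather averages, quantile groupings and the per-state
quadratic teleconnection fits."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MISSING_LABEL",
    "FFB_YIELD_MAX",
    "OER_MAX",
    "compute_ffb_yield",
    "compute_oil_yield",
    "apply_exclusions",
    "encode_missing_category",
    "encode_fertilizer",
    "quantile_groups",
    "rolling_24m_average",
    "daily_to_monthly_precip",
    "fit_quadratic",
    "fit_state_quadratic",
    "describe",
    "DescriptiveSummary",
    "clean_panel",
]

MISSING_LABEL = "MISSING"
FFB_YIELD_MAX = 6.0  # t/ha/month, strict
OER_MAX = 30.0  # percent, strict


def compute_ffb_yield(ffb_mass, harvested_area):
    """FFB yield = mass / harvested area (t/ha/month)."""
    mass = np.asarray(ffb_mass, dtype=float)
    area = np.asarray(harvested_area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("harvested_area must be positive")
    if np.any(mass < 0):
        raise ValueError("ffb_mass must be nonnegative")
    out = mass / area
    return float(out) if out.ndim == 0 else out


def compute_oil_yield(ffb_yield, oer):
    """Oil yield = FFB yield x OER / 100; missing OER propagates to missing."""
    fy = np.asarray(ffb_yield, dtype=float)
    o = np.asarray(oer, dtype=float)
    valid = ~np.isnan(o)
    if np.any((o[valid] < 0) | (o[valid] > 100)):
        raise ValueError("oer must lie in [0, 100]")
    out = fy * o / 100.0
    return float(out) if out.ndim == 0 else out


def apply_exclusions(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop implausible rows: ffb_yield > 6 t/ha/month or OER > 30 %.

    Inequalities are strict (boundary values are kept); missing OER never
    triggers exclusion.  Returns the retained frame (rows untouched) and an
    exclusion log with one row per dropped record and its reason.
    """
    y_bad = df["ffb_yield"].to_numpy(dtype=float) > FFB_YIELD_MAX
    oer = df["oer"].to_numpy(dtype=float) if "oer" in df else np.full(len(df), np.nan)
    o_bad = np.nan_to_num(oer, nan=-np.inf) > OER_MAX
    drop = y_bad | o_bad
    reasons = np.where(
        y_bad & o_bad,
        "ffb_yield>6;oer>30",
        np.where(y_bad, "ffb_yield>6", "oer>30"),
    )
    log = pd.DataFrame(
        {
            "estate_id": df.loc[drop, "estate_id"].to_numpy() if "estate_id" in df else None,
            "period": df.loc[drop, "period"].to_numpy() if "period" in df else None,
            "reason": reasons[drop],
        }
    )
    return df.loc[~drop].copy(), log


def encode_missing_category(values, missing_label: str = MISSING_LABEL) -> pd.Categorical:
    """Code missing values as a dedicated category; non-missing values keep
    their (stringified) value as the level label, so they round-trip."""
    s = pd.Series(values)
    labels = s.map(lambda v: missing_label if pd.isna(v) else str(v))
    cats = sorted(set(labels) - {missing_label}) + (
        [missing_label] if (labels == missing_label).any() else []
    )
    return pd.Categorical(labels, categories=cats)


def encode_fertilizer(values, k: int = 4, missing_label: str = "REF") -> pd.Categorical:
    """Fertilizer-cost coding: zero or missing investment forms the reference
    level; positive costs are binned into ``k`` quantile groups (or a single
    NONZERO level when too few distinct values)."""
    s = pd.Series(values, dtype=float)
    ref = s.isna() | (s == 0)
    out = pd.Series([missing_label] * len(s), index=s.index, dtype=object)
    pos = s[~ref]
    if len(pos) > 0:
        if pos.nunique() >= k:
            out[~ref] = quantile_groups(pos, k).astype(str)
        else:
            out[~ref] = "NONZERO"
    cats = [missing_label] + sorted(set(out) - {missing_label})
    return pd.Categorical(out, categories=cats)


_DEFAULT_LABELS = {
    3: ("low", "medium", "high"),
    4: ("low", "medium-low", "medium-high", "high"),
}


def quantile_groups(values, k: int, labels=None) -> pd.Categorical:
    """Group values by empirical quantiles (linear-interpolation convention);
    ties on a boundary go to the lower group; missing values get their own
    MISSING level."""
    s = pd.Series(values, dtype=float)
    nonmiss = s.dropna()
    if nonmiss.nunique() < k:
        raise ValueError(f"need at least {k} distinct non-missing values")
    if labels is None:
        labels = _DEFAULT_LABELS.get(k, tuple(f"q{i + 1}" for i in range(k)))
    if len(labels) != k:
        raise ValueError("labels must have length k")
    bounds = np.quantile(nonmiss.to_numpy(), np.arange(1, k) / k)
    idx = np.searchsorted(bounds, s.to_numpy(), side="left")
    out = np.array([MISSING_LABEL] * len(s), dtype=object)
    mask = s.notna().to_numpy()
    out[mask] = np.asarray(labels, dtype=object)[idx[mask]]
    cats = list(labels) + ([MISSING_LABEL] if (~mask).any() else [])
    return pd.Categorical(out, categories=cats)


def rolling_24m_average(series: pd.Series, at) -> float:
    """Mean of the 24 values in the current month and the past 23 months."""
    at = pd.Period(at, "M")
    idx = pd.PeriodIndex(series.index, freq="M")
    s = pd.Series(series.to_numpy(dtype=float), index=idx).sort_index()
    window = pd.period_range(at - 23, at, freq="M")
    missing = window.difference(s.index)
    if len(missing) > 0:
        raise ValueError(f"series missing months for 24-month window, e.g. {missing[0]}")
    vals = s.loc[window]
    if vals.isna().any():
        raise ValueError("missing values inside the 24-month window")
    return float(vals.mean())


def daily_to_monthly_precip(mm_per_day):
    """Convert mm/day to mm/month using a fixed 30-day month."""
    out = np.asarray(mm_per_day, dtype=float) * 30.0
    return float(out) if out.ndim == 0 else out


def fit_quadratic(w, x) -> tuple[float, float, float]:
    """OLS fit of ``w = a + b x + c x^2``; errors on a rank-deficient design."""
    w = np.asarray(w, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct x values for a quadratic fit")
    X = np.column_stack([np.ones_like(x), x, x**2])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient quadratic design")
    beta, *_ = np.linalg.lstsq(X, w, rcond=None)
    return tuple(float(b) for b in beta)


def fit_state_quadratic(
    df: pd.DataFrame, weather_col: str, enso: pd.Series, lag: int = 2
) -> pd.DataFrame:
    """Per-state quadratic teleconnection fits of a weather variable on the
    lagged exposure index.

    Returns one row per state with the intercept/linear/quadratic coefficients,
    R-squared and the number of observations.
    """
    idx = pd.PeriodIndex(enso.index, freq="M")
    s = pd.Series(enso.to_numpy(dtype=float), index=idx)
    periods = pd.PeriodIndex(df["period"], freq="M")
    x_all = s.reindex(periods - lag).to_numpy()
    if np.isnan(x_all).any():
        raise ValueError("exposure series does not cover all lagged periods")
    rows = []
    for state, g in df.assign(_x=x_all).groupby("state", sort=True):
        w = g[weather_col].to_numpy(dtype=float)
        x = g["_x"].to_numpy(dtype=float)
        a, b, c = fit_quadratic(w, x)
        resid = w - (a + b * x + c * x**2)
        tss = float(((w - w.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / tss if tss > 0 else np.nan
        rows.append({"state": state, "a": a, "b": b, "c": c, "r2": r2, "n": len(g)})
    return pd.DataFrame(rows)


@dataclass
class DescriptiveSummary:
    numeric: pd.DataFrame  # mean/sd/min/max per variable
    n_obs: int
    n_estates: int
    categorical_counts: dict

    def __post_init__(self) -> None:
        bad = self.numeric[(self.numeric["min"] > self.numeric["mean"]) | (self.numeric["mean"] > self.numeric["max"])]
        if len(bad) > 0:
            raise ValueError(f"inconsistent summary for {list(bad.index)}")


def describe(df: pd.DataFrame) -> DescriptiveSummary:
    """Mean/SD/min/max per numeric column plus level counts per categorical."""
    if len(df) == 0:
        raise ValueError("cannot describe an empty frame")
    num = df.select_dtypes(include=[np.number, bool])
    numeric = pd.DataFrame(
        {
            "mean": num.mean(),
            "sd": num.std(ddof=1),
            "min": num.min(),
            "max": num.max(),
        }
    ).astype(float)
    cats = {}
    for col in df.columns:
        if df[col].dtype == object or isinstance(df[col].dtype, pd.CategoricalDtype):
            cats[col] = df[col].value_counts(dropna=False).to_dict()
    n_estates = df["estate_id"].nunique() if "estate_id" in df else 0
    return DescriptiveSummary(numeric=numeric, n_obs=len(df), n_estates=n_estates, categorical_counts=cats)


def clean_panel(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ensure outcomes are present (recomputing from mass/area and OER where
    needed) and apply the exclusion filters.  Returns (panel, exclusion_log)."""
    df = df.copy()
    if "ffb_yield" not in df:
        df["ffb_yield"] = compute_ffb_yield(df["ffb_mass"], df["harvested_area"])
    if "oil_yield" not in df and "oer" in df:
        df["oil_yield"] = compute_oil_yield(df["ffb_yield"], df["oer"])
    return apply_exclusions(df)
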