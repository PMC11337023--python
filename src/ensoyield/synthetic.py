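"""Synthetic estate-month panel generator with a known exposure-lag-response
surface.

The generator emulates the structure the analysis assumes — a basin-wide
monthly climate index shared by all estates, estate/state heterogeneity,
calendar seasonality with a February trough and a September-October peak, and
state-specific quadratic weather teleconnections to the 2-month-lagged index —
while embedding a configurable ground-truth surface so that downstream
estimators can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "TrueSurface",
    "SimConfig",
    "generate_enso_series",
    "generate_panel",
    "true_cumulative",
    "write_panel_csv",
    "read_panel_csv",
]

# Named RNG substreams so each generation stage is independently reproducible.
_STREAM_ENSO = 11
_STREAM_ESTATES = 23
_STREAM_NOISE = 37
_STREAM_WEATHER = 41
_STREAM_COVARIATES = 53


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), stream)))


# Calendar-month seasonal shape (Jan..Dec), zero mean after centering:
# trough in February, equal peaks in September and October.
_SEASON_SHAPE = np.array(
    [-0.55, -1.0, -0.65, -0.35, -0.10, 0.05, 0.20, 0.45, 1.00, 1.00, 0.55, -0.05]
)
_SEASON_SHAPE = _SEASON_SHAPE - _SEASON_SHAPE.mean()


@dataclass(frozen=True)
class TrueSurface:
    """Ground-truth exposure-lag-response surface.

    ``f(x, l) = -(gamma_pos * max(x,0)^2 + gamma_neg * min(x,0)^2) * w[l]``
    with a nonnegative lag-weight profile ``w`` summing to one over
    ``l = 0..L_true``.  ``gamma_neg > gamma_pos`` gives the larger cool-phase
    (negative-index) effect.
    """

    gamma_pos: float = 0.05
    gamma_neg: float = 0.10
    L_true: int = 12
    lag_profile: str = "geometric"  # or "uniform"
    decay: float = 0.7

    def weights(self) -> np.ndarray:
        l = np.arange(self.L_true + 1)
        if self.lag_profile == "uniform":
            w = np.ones(self.L_true + 1)
        elif self.lag_profile == "geometric":
            w = self.decay**l
        else:
            raise ValueError(f"unknown lag_profile {self.lag_profile!r}")
        return w / w.sum()

    def intensity(self, x) -> np.ndarray:
        """Cumulative (lag-summed) effect of exposure x: ``-(g+ x+^2 + g- x-^2)``."""
        x = np.asarray(x, dtype=float)
        return -(self.gamma_pos * np.maximum(x, 0.0) ** 2 + self.gamma_neg * np.minimum(x, 0.0) ** 2)

    def f(self, x, l) -> np.ndarray:
        w = self.weights()
        l = np.asarray(l, dtype=int)
        wl = np.where((l >= 0) & (l <= self.L_true), w[np.clip(l, 0, self.L_true)], 0.0)
        return self.intensity(x) * wl


def true_cumulative(surface: TrueSurface, x, L: int):
    """Exact cumulative effect ``sum_{l=0}^{L} f(x, l)``; requires L >= L_true."""
    if L < surface.L_true:
        raise ValueError(f"L={L} does not cover the true lag window 0..{surface.L_true}")
    return surface.intensity(x)


@dataclass
class SimConfig:
    n_estates: int = 200
    n_states: int = 13
    panel_start: str = "2015-01"
    panel_end: str = "2023-06"
    history_months: int = 30  # index history generated before panel_start

    # exposure process: stationary AR(1) plus deterministic event offsets
    enso_ar_coef: float = 0.85
    enso_sd: float = 0.30
    event_offsets: list = field(
        default_factory=lambda: [
            ("2015-03", "2016-04", 1.8),
            ("2018-09", "2019-06", 0.7),
            ("2020-08", "2021-03", -1.1),
            ("2021-08", "2022-06", -1.0),
            ("2023-03", "2023-06", 1.2),
        ]
    )

    surface: TrueSurface = field(default_factory=TrueSurface)
    oer_surface: TrueSurface = field(
        default_factory=lambda: TrueSurface(gamma_pos=0.1, gamma_neg=0.15, L_true=6)
    )

    season_amp: float = 0.25
    oer_season_amp: float = 0.4
    state_effect_sd: float = 0.15
    estate_intercept_sd: float = 0.20
    estate_noise_ar: float = 0.0  # optional AR(1) in the estate-month noise
    noise_sd: float = 0.35
    oer_noise_sd: float = 1.5
    mean_yield: float = 1.36
    mean_oer: float = 18.71

    # covariate distributions / true effects (labor and age are true signals
    # for covariate screening; the rest are null)
    labor_mean: float = 0.04  # workers/ha
    labor_sd_log: float = 0.4
    labor_effect: float = 2.0  # t/ha per worker/ha above the mean
    age_effect: float = -0.01  # t/ha per year above the mean age
    lockdown_effect: float = -0.03
    fertilizer_effect: float = 0.05  # any-investment bump
    mean_fertilizer_cost: float = 1135.28  # thousand MYR among investors
    frac_fertilizer_zero: float = 0.25
    frac_fertilizer_missing: float = 0.10
    frac_soil_missing: float = 0.45

    # state-specific weather teleconnection quadratics (a, b, c) in lag-2 index;
    # generated from the seed when None
    weather_coefs: dict | None = None
    weather_noise_sd: float = 0.30

    seed: int = 0

    def periods(self) -> pd.PeriodIndex:
        return pd.period_range(self.panel_start, self.panel_end, freq="M")

    def validate(self) -> None:
        if len(self.periods()) < 24:
            raise ValueError("panel must span at least 24 months")
        for name in (
            "enso_sd",
            "season_amp",
            "state_effect_sd",
            "estate_intercept_sd",
            "noise_sd",
            "oer_noise_sd",
            "weather_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1 < self.enso_ar_coef < 1:
            raise ValueError("enso_ar_coef must lie in (-1, 1)")
        if not 0 < self.mean_oer < 30:
            raise ValueError("mean_oer must lie in (0, 30)")
        if self.n_estates < 1 or self.n_states < 1:
            raise ValueError("need at least one estate and one state")
        if self.history_months < max(24, self.surface.L_true + 1):
            raise ValueError("history_months must cover 24 months and the true lag window")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["surface"] = asdict(self.surface)
        d["oer_surface"] = asdict(self.oer_surface)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if isinstance(d.get("surface"), dict):
            d["surface"] = TrueSurface(**d["surface"])
        if isinstance(d.get("oer_surface"), dict):
            d["oer_surface"] = TrueSurface(**d["oer_surface"])
        if isinstance(d.get("event_offsets"), list):
            d["event_offsets"] = [tuple(e) for e in d["event_offsets"]]
        return cls(**d)


def generate_enso_series(config: SimConfig) -> pd.Series:
    """Stationary AR(1) monthly index plus deterministic event offsets.

    One value per calendar month, starting ``history_months`` before the panel
    and shared by every estate.
    """
    config.validate()
    panel = config.periods()
    start = panel[0] - config.history_months
    idx = pd.period_range(start, panel[-1], freq="M")
    rng = _rng(config.seed, _STREAM_ENSO)
    n = len(idx)
    phi, sd = config.enso_ar_coef, config.enso_sd
    x = np.zeros(n)
    if sd > 0:
        x[0] = rng.normal(0.0, sd / np.sqrt(1.0 - phi**2))
        eps = rng.normal(0.0, sd, size=n - 1)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + eps[t - 1]
    for start_m, end_m, level in config.event_offsets:
        lo, hi = pd.Period(start_m, "M"), pd.Period(end_m, "M")
        mask = (idx >= lo) & (idx <= hi)
        x[np.asarray(mask)] += float(level)
    return pd.Series(x, index=idx, name="enso")


def _surface_effect(series: pd.Series, surface: TrueSurface, periods: pd.PeriodIndex) -> np.ndarray:
    """Per-month cumulative lag effect: FIR filter of the intensity series."""
    g = surface.intensity(series.to_numpy())
    w = surface.weights()
    full = np.convolve(g, w)[: len(series)]
    pos = periods.asi8 - series.index[0].ordinal
    if pos.min() < surface.L_true:
        raise ValueError("exposure series does not cover the true lag window")
    return full[pos]


def generate_panel(config: SimConfig, enso: pd.Series | None = None) -> pd.DataFrame:
    """Generate the estate-month panel as a tidy DataFrame.

    Columns: estate_id, state, period, harvested_area, ffb_mass, ffb_yield,
    oer, oil_yield, labor_intensity, fertilizer_cost, age_profile, soil_score,
    covid_cases, lockdown, price_cpo, price_fertilizer, cpi, fx_rate,
    air_temp, soil_temp, precip.
    """
    config.validate()
    if enso is None:
        enso = generate_enso_series(config)
    periods = config.periods()
    n_e, n_t = config.n_estates, len(periods)
    months = periods.month.to_numpy()
    years = periods.year.to_numpy()

    rng_est = _rng(config.seed, _STREAM_ESTATES)
    rng_noise = _rng(config.seed, _STREAM_NOISE)
    rng_wx = _rng(config.seed, _STREAM_WEATHER)
    rng_cov = _rng(config.seed, _STREAM_COVARIATES)

    # estate-level structure
    states = np.array([f"S{(i % config.n_states) + 1:02d}" for i in range(n_e)])
    state_levels = sorted(set(states))
    state_eff = dict(
        zip(state_levels, rng_est.normal(0.0, config.state_effect_sd, size=len(state_levels)))
    )
    estate_int = rng_est.normal(0.0, config.estate_intercept_sd, size=n_e)
    harvested_area = np.exp(rng_est.normal(np.log(200.0), 0.5, size=n_e))
    labor = np.exp(rng_est.normal(np.log(config.labor_mean), config.labor_sd_log, size=n_e))
    age = rng_est.uniform(2.0, 28.0, size=n_e)
    soil = rng_est.uniform(1.0, 7.0, size=n_e)
    soil[rng_est.random(n_e) < config.frac_soil_missing] = np.nan

    # fertilizer cost per estate-year (annual reporting)
    year_levels = np.unique(years)
    fert = np.empty((n_e, len(year_levels)))
    for j, _y in enumerate(year_levels):
        u = rng_cov.random(n_e)
        cost = np.exp(rng_cov.normal(np.log(config.mean_fertilizer_cost), 0.6, size=n_e))
        fert[:, j] = np.where(
            u < config.frac_fertilizer_missing,
            np.nan,
            np.where(u < config.frac_fertilizer_missing + config.frac_fertilizer_zero, 0.0, cost),
        )

    # common monthly economic series (positive random walks)
    def _walk(base, sd):
        return base * np.exp(np.cumsum(rng_cov.normal(0.0, sd, size=n_t)))

    price_cpo = _walk(2500.0, 0.03)
    price_fert = _walk(300.0, 0.03)
    cpi = _walk(100.0, 0.004)
    fx = _walk(4.2, 0.01)

    covid = np.where(
        periods >= pd.Period("2020-03", "M"), rng_cov.poisson(2000.0, size=n_t), 0
    ).astype(int)
    lockdown_window = (periods >= pd.Period("2020-03", "M")) & (periods <= pd.Period("2021-12", "M"))
    state_locks = {s: rng_cov.random() < 0.8 for s in state_levels}

    # monthly exposure-driven components (shared across estates)
    surf_ffb = _surface_effect(enso, config.surface, periods)
    surf_oer = _surface_effect(enso, config.oer_surface, periods)
    season = config.season_amp * _SEASON_SHAPE[months - 1]
    oer_season = config.oer_season_amp * _SEASON_SHAPE[months - 1]

    # weather: state-specific quadratic in the 2-month-lagged index
    x_lag2 = enso.to_numpy()[periods.asi8 - enso.index[0].ordinal - 2]
    coefs = config.weather_coefs
    if coefs is None:
        coefs = {
            s: {
                "air_temp": (26.24 + rng_wx.normal(0, 0.5), rng_wx.normal(0.4, 0.1), rng_wx.normal(0.05, 0.03)),
                "soil_temp": (27.0 + rng_wx.normal(0, 0.5), rng_wx.normal(0.3, 0.1), rng_wx.normal(0.05, 0.03)),
                "precip": (7.09 + rng_wx.normal(0, 1.0), rng_wx.normal(-0.8, 0.3), rng_wx.normal(-0.3, 0.15)),
            }
            for s in state_levels
        }

    # estate-month noise, optionally AR(1) within estate
    eps = rng_noise.normal(0.0, config.noise_sd, size=(n_e, n_t))
    if config.estate_noise_ar:
        phi = config.estate_noise_ar
        eps[:, 0] /= np.sqrt(1 - phi**2)
        for t in range(1, n_t):
            eps[:, t] += phi * eps[:, t - 1]
    eps_oer = rng_noise.normal(0.0, config.oer_noise_sd, size=(n_e, n_t))
    eps_wx = rng_noise.normal(0.0, config.weather_noise_sd, size=(3, n_e, n_t))

    year_col = np.searchsorted(year_levels, years)
    fert_month = fert[:, year_col]  # (n_e, n_t)
    invested = np.nan_to_num(fert_month) > 0

    ffb = (
        config.mean_yield
        + season[None, :]
        + np.array([state_eff[s] for s in states])[:, None]
        + estate_int[:, None]
        + surf_ffb[None, :]
        + config.labor_effect * (labor - config.labor_mean)[:, None]
        + config.age_effect * (age - 15.0)[:, None]
        + config.fertilizer_effect * invested
        + eps
    )

    lock = np.zeros((n_e, n_t), dtype=bool)
    for i, s in enumerate(states):
        if state_locks[s]:
            lock[i, :] = np.asarray(lockdown_window)
    ffb = ffb + config.lockdown_effect * lock
    ffb = np.clip(ffb, 0.0, None)

    oer = np.clip(config.mean_oer + oer_season[None, :] + surf_oer[None, :] + eps_oer, 0.0, None)

    wx = {}
    for k, key in enumerate(("air_temp", "soil_temp", "precip")):
        a = np.array([coefs[s][key][0] for s in states])[:, None]
        b = np.array([coefs[s][key][1] for s in states])[:, None]
        c = np.array([coefs[s][key][2] for s in states])[:, None]
        w = a + b * x_lag2[None, :] + c * x_lag2[None, :] ** 2 + eps_wx[k]
        if key == "precip":
            w = np.clip(w, 0.0, None)
        wx[key] = w

    df = pd.DataFrame(
        {
            "estate_id": np.repeat([f"E{i:05d}" for i in range(n_e)], n_t),
            "state": np.repeat(states, n_t),
            "period": np.tile(periods.astype(str), n_e),
            "harvested_area": np.repeat(harvested_area, n_t),
            "ffb_yield": ffb.ravel(),
            "oer": oer.ravel(),
            "labor_intensity": np.repeat(labor, n_t),
            "fertilizer_cost": fert_month.ravel(),
            "age_profile": np.repeat(age, n_t),
            "soil_score": np.repeat(soil, n_t),
            "covid_cases": np.tile(covid, n_e),
            "lockdown": lock.ravel(),
            "price_cpo": np.tile(price_cpo, n_e),
            "price_fertilizer": np.tile(price_fert, n_e),
            "cpi": np.tile(cpi, n_e),
            "fx_rate": np.tile(fx, n_e),
            "air_temp": wx["air_temp"].ravel(),
            "soil_temp": wx["soil_temp"].ravel(),
            "precip": wx["precip"].ravel(),
        }
    )
    df["ffb_mass"] = df["ffb_yield"] * df["harvested_area"]
    df["oil_yield"] = df["ffb_yield"] * df["oer"] / 100.0
    return df


def write_panel_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.8g")


def read_panel_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"estate_id": str, "state": str, "period": str})
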