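import numpy as np
import pandas as pd
import pytest

from ensoyield.lagbasis import (
    BasisSpec,
    CrossBasis,
    build_crossbasis,
    build_exposure_history,
    quadratic_exposure_spec,
)
from ensoyield.modelfit import (
    ModelSpec,
    fit_fixed,
    fit_random_intercept,
    gaussian_aic,
    select_max_lag,
    wald_crossbasis,
)
from ensoyield.synthetic import SimConfig, TrueSurface, generate_enso_series, generate_panel

from conftest import TRUE_COVARIATES, simulate_and_fit


def _toy_panel(rng, n_estates=6, months=30):
    periods = pd.period_range("2018-01", periods=months, freq="M")
    rows = []
    for i in range(n_estates):
        for p in periods:
            rows.append(
                {
                    "estate_id": f"E{i}",
                    "state": "S1" if i % 2 else "S2",
                    "period": str(p),
                    "z": rng.normal(),
                }
            )
    return pd.DataFrame(rows)


def _toy_cb(rng, n):
    W = rng.normal(size=(n, 2))
    return CrossBasis(
        W=W,
        x_spec=BasisSpec(degree=1, boundary=(-3, 3), internal_knots=(0.0,)),
        l_spec=BasisSpec(degree=1, boundary=(0, 1), include_intercept=True),
        L=1,
        column_names=["cb_a", "cb_b"],
    )


class TestFitFixed:
    def test_noiseless_interpolation(self, rng):
        df = _toy_panel(rng)
        cb = _toy_cb(rng, len(df))
        months = pd.PeriodIndex(df["period"], freq="M").month
        y = 1.0 + 0.5 * cb.W[:, 0] - 0.25 * cb.W[:, 1] + 0.1 * (months == 3) + 0.3 * df["z"]
        df["y"] = y
        fit = fit_fixed(df, ModelSpec(outcome="y", covariates=("z",)), cb)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert fit.params["cb_a"] == pytest.approx(0.5, abs=1e-8)
        assert fit.params["cb_b"] == pytest.approx(-0.25, abs=1e-8)
        assert fit.params["z"] == pytest.approx(0.3, abs=1e-8)

    def test_aic_oracle(self, rng):
        n = 50
        X = rng.normal(size=(n, 3))
        y = X @ np.array([1.0, 0.5, -1.0]) + rng.normal(0, 1, n)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["estate_id"] = "E0"
        df["state"] = "S1"
        df["period"] = "2020-01"
        df["y"] = y
        fit = fit_fixed(
            df, ModelSpec(outcome="y", covariates=("a", "b", "c"), month_fe=False, state_fe=False), None
        )
        # independent AIC recomputation: Gaussian ML log-likelihood
        Xd = np.column_stack([np.ones(n), X])
        beta = np.linalg.lstsq(Xd, y, rcond=None)[0]
        rss = ((y - Xd @ beta) ** 2).sum()
        loglik = -n / 2 * (np.log(2 * np.pi * rss / n) + 1)
        assert fit.aic == pytest.approx(-2 * loglik + 2 * (4 + 1), rel=1e-12)

    def test_rank_deficiency_lists_aliased(self, rng):
        df = _toy_panel(rng)
        df["z2"] = df["z"] * 2.0
        cb = _toy_cb(rng, len(df))
        df["y"] = rng.normal(size=len(df))
        with pytest.raises(ValueError, match="aliased"):
            fit_fixed(df, ModelSpec(outcome="y", covariates=("z", "z2")), cb)

    def test_zero_column_rejected(self, rng):
        df = _toy_panel(rng)
        df["zero"] = 0.0
        df["y"] = rng.normal(size=len(df))
        cb = _toy_cb(rng, len(df))
        with pytest.raises(ValueError, match="aliased"):
            fit_fixed(df, ModelSpec(outcome="y", covariates=("zero",)), cb)

    def test_missing_outcome_rows_dropped(self, rng):
        df = _toy_panel(rng)
        cb = _toy_cb(rng, len(df))
        df["y"] = rng.normal(size=len(df))
        df.loc[df.index[:10], "y"] = np.nan
        fit = fit_fixed(df, ModelSpec(outcome="y"), cb)
        assert fit.n == len(df) - 10

    def test_reference_level_invariance(self):
        from ensoyield.association import cumulative_association

        cfg = SimConfig(n_estates=15, seed=21, surface=TrueSurface(0.05, 0.1, 6))
        enso = generate_enso_series(cfg)
        panel = generate_panel(cfg, enso)
        periods = pd.PeriodIndex(panel["period"], freq="M")
        Q = build_exposure_history(enso, periods, 12)
        cb = build_crossbasis(Q)
        states = sorted(panel["state"].unique())
        f1 = fit_fixed(panel, ModelSpec(outcome="ffb_yield", drop_state=states[0], drop_month=1), cb)
        f2 = fit_fixed(panel, ModelSpec(outcome="ffb_yield", drop_state=states[2], drop_month=6), cb)
        c1 = cumulative_association(f1, cb, [1.0, -0.5])
        c2 = cumulative_association(f2, cb, [1.0, -0.5])
        np.testing.assert_allclose(c1.effect, c2.effect, atol=1e-8)
        np.testing.assert_allclose(c1.se, c2.se, atol=1e-8)

    def test_covariance_psd(self, fitted_small):
        fit, *_ = fitted_small
        eigvals = np.linalg.eigvalsh(fit.cov.to_numpy())
        assert eigvals.min() > -1e-10
        assert np.isfinite(fit.aic)


class TestWaldNull:
    def test_type_one_error_rate(self):
        # null panels: whole-block Wald rejects at roughly the nominal rate
        rejections = 0
        reps = 40
        for s in range(reps):
            cfg = SimConfig(
                n_estates=30,
                seed=90_000 + s,
                estate_intercept_sd=0.0,
                fertilizer_effect=0.0,
                surface=TrueSurface(0.0, 0.0),
                oer_surface=TrueSurface(0.0, 0.0, L_true=6),
            )
            fit, cb, _, _ = simulate_and_fit(cfg, L=12)
            _, p = wald_crossbasis(fit)
            rejections += p < 0.05
        assert rejections <= 7  # ~95 % non-significant, binomial slack


class TestSelectMaxLag:
    def test_single_candidate(self, small_panel, small_enso):
        spec = ModelSpec(outcome="ffb_yield", covariates=TRUE_COVARIATES)
        L, table, fit, cb = select_max_lag(small_panel, spec, small_enso, [10])
        assert L == 10 and len(table) == 1 and cb.L == 10

    def test_tie_breaks_to_smaller(self, monkeypatch, small_panel, small_enso):
        import ensoyield.modelfit as mf

        monkeypatch.setattr(mf, "gaussian_aic", lambda rss, n, p: 42.0)
        spec = ModelSpec(outcome="ffb_yield", covariates=TRUE_COVARIATES)
        L, table, *_ = mf.select_max_lag(small_panel, spec, small_enso, [23, 10])
        assert L == 10
        assert (table["aic"] == 42.0).all()

    def test_noise_outcome_aic_flat(self, rng, small_panel, small_enso):
        # pure-noise outcome: AIC differences stay within the 2p penalty scale
        df = small_panel.copy()
        df["pure_noise"] = rng.normal(size=len(df))
        spec = ModelSpec(outcome="pure_noise")
        _, table, *_ = select_max_lag(df, spec, small_enso, [6, 12, 23])
        spread = table["aic"].max() - table["aic"].min()
        assert spread < 2 * table["p"].max()


class TestRandomIntercept:
    def _one_way(self, rng, m=40, k=12, sd_b=0.5, sd_e=0.3):
        g = np.repeat(np.arange(m), k)
        b = rng.normal(0, sd_b, m)
        y = 2.0 + b[g] + rng.normal(0, sd_e, m * k)
        return pd.DataFrame(
            {"estate_id": g.astype(str), "y": y, "period": "2020-01", "state": "S1"}
        ), y.reshape(m, k)

    def test_balanced_anova_oracle(self, rng):
        df, ymat = self._one_way(rng)
        m, k = ymat.shape
        fit = fit_random_intercept(df, ModelSpec(outcome="y", month_fe=False, state_fe=False), None)
        gm = ymat.mean(axis=1)
        msb = k * np.var(gm, ddof=1)
        msw = ((ymat - gm[:, None]) ** 2).sum() / (m * (k - 1))
        assert fit.sigma2_b == pytest.approx((msb - msw) / k, rel=0.01)
        assert fit.sigma2 == pytest.approx(msw, rel=0.01)

    def test_zero_between_variance(self, rng):
        df, _ = self._one_way(rng, sd_b=0.0)
        spec = ModelSpec(outcome="y", month_fe=False, state_fe=False)
        ri = fit_random_intercept(df, spec, None)
        fx = fit_fixed(df, spec, None)
        assert ri.sigma2_b < 0.05 * ri.sigma2
        # balanced design: GLS equals OLS for the mean regardless of components
        assert ri.params["const"] == pytest.approx(fx.params["const"], abs=1e-6)

    def test_needs_repeated_groups(self, rng):
        df = pd.DataFrame(
            {"estate_id": ["a", "b", "c"], "y": rng.normal(size=3), "period": "2020-01", "state": "S"}
        )
        with pytest.raises(ValueError):
            fit_random_intercept(df, ModelSpec(outcome="y", month_fe=False, state_fe=False), None)

    def test_estate_sd_recovery_small(self):
        # planted estate SD recovered at modest panel size (full-size check
        # lives in the acceptance suite)
        cfg = SimConfig(n_estates=120, seed=17, estate_intercept_sd=0.3)
        enso = generate_enso_series(cfg)
        panel = generate_panel(cfg, enso)
        periods = pd.PeriodIndex(panel["period"], freq="M")
        Q = build_exposure_history(enso, periods, 12)
        cb = build_crossbasis(Q, x_spec=quadratic_exposure_spec(Q))
        fit = fit_random_intercept(
            panel, ModelSpec(outcome="ffb_yield", covariates=TRUE_COVARIATES), cb
        )
        assert np.sqrt(fit.sigma2_b) == pytest.approx(0.3, rel=0.25)


def test_gaussian_aic_formula():
    n, p, rss = 100, 5, 37.5
    expected = n * np.log(rss / n) + 2 * (p + 1) + n * (1 + np.log(2 * np.pi))
    assert gaussian_aic(rss, n, p) == expected
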