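import numpy as np
import pandas as pd
import pytest

from ensoyield.lagbasis import build_crossbasis, build_exposure_history, default_exposure_spec
from ensoyield.modelfit import ModelSpec, fit_fixed
from ensoyield.synthetic import SimConfig, TrueSurface, generate_enso_series, generate_panel

# covariates whose true effects the generator embeds
TRUE_COVARIATES = ("labor_intensity", "age_profile", "lockdown")


def simulate_and_fit(cfg, L=23, x_spec=None, outcome="ffb_yield", covariates=TRUE_COVARIATES):
    """Generate a panel, build the cross-basis at max lag L, fit by OLS."""
    enso = generate_enso_series(cfg)
    panel = generate_panel(cfg, enso)
    periods = pd.PeriodIndex(panel["period"], freq="M")
    Q = build_exposure_history(enso, periods, L)
    cb = build_crossbasis(Q, x_spec=x_spec if x_spec is not None else default_exposure_spec(Q))
    fit = fit_fixed(panel, ModelSpec(outcome=outcome, covariates=covariates), cb)
    return fit, cb, panel, enso


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_estates=20, seed=7)


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return generate_panel(small_cfg)


@pytest.fixture(scope="session")
def small_enso(small_cfg):
    return generate_enso_series(small_cfg)


@pytest.fixture(scope="session")
def fitted_small():
    """One medium-signal fit shared by identity-style tests."""
    cfg = SimConfig(
        n_estates=30,
        seed=11,
        estate_intercept_sd=0.0,
        surface=TrueSurface(gamma_pos=0.1, gamma_neg=0.2, L_true=12),
    )
    fit, cb, panel, enso = simulate_and_fit(cfg)
    return fit, cb, panel, enso


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
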