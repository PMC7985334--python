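import numpy as np
import pandas as pd
import pytest

from tvcpar.ema_io import CODE_OBSERVED, StressSeries, modeling_view
from tvcpar.synthetic_data import MissingnessSpec, RegimeSpec, simulate_stress_series
from tvcpar.tvcp_ar import LagPairSet, build_lag_pairs

NO_MISSING = MissingnessSpec()


def make_series(values, codes=None, patient_id="t", epoch_minutes=3):
    """A regular series from explicit values (NaN => absent_row)."""
    values = np.asarray(values, dtype=float)
    if codes is None:
        codes = np.where(np.isfinite(values), 0, 3)
    return StressSeries(
        patient_id=patient_id,
        epoch_start="2020-01-06T00:00:00Z",
        values=values,
        codes=codes,
        epoch_minutes=epoch_minutes,
    )


def truncate(series, n):
    """First n slots of a regular series."""
    return StressSeries(
        patient_id=series.patient_id,
        epoch_start=series.epoch_start,
        values=series.values[:n],
        codes=series.codes[:n],
        epoch_minutes=series.epoch_minutes,
    )


def ar1_pairs(n, phi, intercept=10.0, noise_sd=5.0, seed=0):
    """Lag pairs from a plain stationary AR(1), no rounding or clipping."""
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    xp = intercept / (1.0 - phi)
    for t in range(n):
        xp = intercept + phi * xp + rng.normal(0.0, noise_sd)
        x[t] = xp
    return LagPairSet(
        t_index=np.arange(1, n),
        y_prev=x[:-1],
        y_curr=x[1:],
        segment_id=np.zeros(n - 1, dtype=np.int64),
    )


def ols_ar1(y_prev, y_curr):
    """Ordinary least-squares AR(1): returns (intercept, slope)."""
    slope, intercept = np.polyfit(y_prev, y_curr, 1)
    return intercept, slope


@pytest.fixture(scope="session")
def stationary_series():
    """2000-slot stationary AR(1) stress series, phi=0.5, fully observed."""
    s, _ = simulate_stress_series(
        [RegimeSpec(0, 20.0, 0.5)], NO_MISSING,
        n_days=5, epoch_minutes=3, noise_sd=5.0, seed=11,
    )
    return truncate(s, 2000)


@pytest.fixture(scope="session")
def stationary_pairs(stationary_series):
    return build_lag_pairs(modeling_view(stationary_series))


@pytest.fixture(scope="session")
def step_series():
    """6000 slots with one strong CP at 3000: intercept 26->14 (3 noise SDs
    down), AR 0.3->0.8."""
    s, _ = simulate_stress_series(
        [RegimeSpec(0, 26.0, 0.3), RegimeSpec(3000, 14.0, 0.8)],
        NO_MISSING, n_days=13, epoch_minutes=3, noise_sd=4.0, seed=99,
    )
    return truncate(s, 6000)


@pytest.fixture(scope="session")
def table2():
    from tvcpar.outcome_stats import case_series_outcomes

    return case_series_outcomes()
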