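"""Synthetic EMA stress series with piecewise time-varying AR(1) dynamics.

Real wearable stress series of this kind are held under restricted access,
so the package ships a generator that emulates their statistical structure:
a 14-day grid of 3-minute epochs (6,720 slots), a latent AR(1) process whose
intercept and autoregressive coefficient drift smoothly within regimes and
jump abruptly between them, observations clipped to the device's [0, 100]
scale and rounded to integers, and the two device missingness mechanisms
(-1 insufficient data, -2 physical activity) plus wholly absent rows.

The latent state evolves unclipped; clipping applies to observations only,
so the AR dynamics are not distorted at the scale boundaries and parameter
recovery targets stay analytically clean.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ema_io import (
    CODE_ABSENT,
    CODE_ACTIVITY,
    CODE_INSUFFICIENT,
    CODE_OBSERVED,
    StressSeries,
)

__all__ = [
    "RegimeSpec",
    "MissingnessSpec",
    "SimulationTruth",
    "simulate_stress_series",
    "simulate_cohort",
    "random_regimes",
]

#: Valid score ranges of the four outcome instruments.
INSTRUMENT_RANGES: dict[str, tuple[float, float]] = {
    "hscl11": (1.0, 4.0),
    "oq30": (0.0, 4.0),
    "gad7": (0.0, 21.0),
    "phq9": (0.0, 27.0),
}

#: Typical baseline (mean, SD) per instrument, on the scale of a clinical
#: outpatient population starting treatment.
_BASELINE_MOMENTS = {
    "hscl11": (2.2, 0.5),
    "oq30": (1.9, 0.45),
    "gad7": (12.0, 3.5),
    "phq9": (14.0, 4.5),
}


@dataclasses.dataclass(frozen=True)
class RegimeSpec:
    """Parameters of one AR(1) regime.

    Within the regime, at epoch ``t``::

        intercept(t) = intercept_base
                       + drift_amplitude_intercept * sin(2*pi*(t - start)/drift_period)
        ar(t)        = ar_base
                       + drift_amplitude_ar * sin(2*pi*(t - start)/drift_period)

    Stationarity at every instant requires |ar_base| + |drift_amplitude_ar| < 1.
    """

    start_epoch: int
    intercept_base: float
    ar_base: float
    drift_amplitude_intercept: float = 0.0
    drift_amplitude_ar: float = 0.0
    drift_period: float = 480.0  # one day of 3-min epochs

    def __post_init__(self) -> None:
        if abs(self.ar_base) + abs(self.drift_amplitude_ar) >= 1.0:
            raise ValueError(
                "non-stationary regime: |ar_base| + |drift_amplitude_ar| "
                f"= {abs(self.ar_base) + abs(self.drift_amplitude_ar):.3f} >= 1"
            )
        if self.drift_period <= 0:
            raise ValueError("drift_period must be positive")


@dataclasses.dataclass(frozen=True)
class MissingnessSpec:
    """Device missingness mechanisms.

    * ``p_insufficient`` — i.i.d. per-epoch probability of code -1.
    * ``activity_block_rate`` / ``activity_block_length`` — physical
      activity (-2) arrives in contiguous blocks (exercise is episodic):
      blocks per day are Poisson, block length is geometric with the given
      mean.
    * ``p_row_dropped`` — i.i.d. probability that an epoch's row is absent
      from the export entirely.
    """

    p_insufficient: float = 0.0
    activity_block_rate: float = 0.0
    activity_block_length: float = 1.0
    p_row_dropped: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_insufficient", "p_row_dropped"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.activity_block_rate < 0:
            raise ValueError("activity_block_rate must be >= 0")
        if self.activity_block_length < 1:
            raise ValueError("activity_block_length must be >= 1 epoch")

    @classmethod
    def realistic(cls) -> "MissingnessSpec":
        """Defaults emulating a reasonably adherent wearer: ~5% epochs with
        insufficient data, two activity blocks/day of ~30 min, 1% dropped
        rows."""
        return cls(
            p_insufficient=0.05,
            activity_block_rate=2.0,
            activity_block_length=10.0,
            p_row_dropped=0.01,
        )


@dataclasses.dataclass
class SimulationTruth:
    """Ground truth of one simulated series, for recovery checks.

    ``missing_mask`` uses the same codes as :mod:`tvcpar.ema_io`
    (0 observed, 1 insufficient, 2 activity, 3 absent row).
    """

    cp_epochs: list[int]
    intercept_curve: np.ndarray
    ar_curve: np.ndarray
    missing_mask: np.ndarray

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "cp_epochs": [int(c) for c in self.cp_epochs],
                "intercept_curve": np.asarray(self.intercept_curve).tolist(),
                "ar_curve": np.asarray(self.ar_curve).tolist(),
                "missing_mask": np.asarray(self.missing_mask).astype(int).tolist(),
            },
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def _parameter_curves(
    regimes: list[RegimeSpec], n: int
) -> tuple[np.ndarray, np.ndarray]:
    if not regimes:
        raise ValueError("at least one regime is required")
    starts = [r.start_epoch for r in regimes]
    if starts[0] != 0:
        raise ValueError("first regime must start at epoch 0")
    if any(b <= a for a, b in zip(starts, starts[1:])):
        raise ValueError("regime start epochs must be strictly increasing")
    if starts[-1] >= n:
        raise ValueError("regime start beyond grid length")
    intercept = np.empty(n)
    ar = np.empty(n)
    bounds = starts + [n]
    for reg, a, b in zip(regimes, bounds[:-1], bounds[1:]):
        t = np.arange(a, b)
        phase = np.sin(2.0 * np.pi * (t - reg.start_epoch) / reg.drift_period)
        intercept[a:b] = reg.intercept_base + reg.drift_amplitude_intercept * phase
        ar[a:b] = reg.ar_base + reg.drift_amplitude_ar * phase
    return intercept, ar


def simulate_stress_series(
    regimes: list[RegimeSpec],
    missing: MissingnessSpec,
    n_days: int = 14,
    epoch_minutes: int = 3,
    noise_sd: float = 8.0,
    seed: int | np.random.Generator = 0,
    patient_id: str = "sim",
    epoch_start: str | pd.Timestamp = "2020-01-06T00:00:00Z",
) -> tuple[StressSeries, SimulationTruth]:
    """Simulate one patient's stress series plus its ground truth.

    The latent process is ``x_t = b0(t) + b1(t) * x_{t-1} + e_t`` with
    ``e_t ~ N(0, noise_sd^2)`` and piecewise smoothly drifting parameter
    curves (see :class:`RegimeSpec`).  Observations are the latent values
    clipped to [0, 100] and rounded to integers; missingness is applied
    after generation with precedence absent-row > activity > insufficient.

    Identical seed implies identical output.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if epoch_minutes < 1 or 1440 % epoch_minutes != 0:
        raise ValueError("epoch_minutes must divide 1440")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    n = n_days * 1440 // epoch_minutes
    if n == 0:
        raise ValueError("empty grid")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    intercept, ar = _parameter_curves(regimes, n)

    # Latent AR(1) recursion, started at the instantaneous fixed point.
    x = np.empty(n)
    eps = rng.normal(0.0, noise_sd, size=n)
    x_prev = intercept[0] / (1.0 - ar[0])
    for t in range(n):
        x_prev = intercept[t] + ar[t] * x_prev + eps[t]
        x[t] = x_prev
    observed = np.clip(np.rint(x), 0, 100)

    # Missingness masks.
    mask = np.full(n, CODE_OBSERVED, dtype=np.int8)
    if missing.p_insufficient > 0:
        mask[rng.random(n) < missing.p_insufficient] = CODE_INSUFFICIENT
    if missing.activity_block_rate > 0:
        epochs_per_day = 1440 // epoch_minutes
        n_blocks = rng.poisson(missing.activity_block_rate, size=n_days)
        for day, k in enumerate(n_blocks):
            for _ in range(int(k)):
                start = day * epochs_per_day + int(
                    rng.integers(0, epochs_per_day)
                )
                length = int(rng.geometric(1.0 / missing.activity_block_length))
                mask[start : min(start + length, n)] = CODE_ACTIVITY
    if missing.p_row_dropped > 0:
        mask[rng.random(n) < missing.p_row_dropped] = CODE_ABSENT

    values = observed.astype(float)
    values[mask != CODE_OBSERVED] = np.nan
    series = StressSeries(
        patient_id=patient_id,
        epoch_start=epoch_start,
        values=values,
        codes=mask.copy(),
        epoch_minutes=epoch_minutes,
    )
    truth = SimulationTruth(
        cp_epochs=[r.start_epoch for r in regimes[1:]],
        intercept_curve=intercept,
        ar_curve=ar,
        missing_mask=mask.copy(),
    )
    return series, truth


def random_regimes(
    n_cps: int,
    n_epochs: int,
    rng: np.random.Generator,
    *,
    min_separation: int = 400,
    intercept_range: tuple[float, float] = (30.0, 55.0),
    intercept_jump: tuple[float, float] = (10.0, 20.0),
    ar_range: tuple[float, float] = (0.45, 0.75),
    ar_jump: tuple[float, float] = (0.15, 0.35),
    drift_amplitude_intercept: float = 3.0,
    drift_amplitude_ar: float = 0.05,
) -> list[RegimeSpec]:
    """Draw a random piecewise regime structure with ``n_cps`` change points.

    Jump magnitudes default to values at which detection is neither trivial
    nor hopeless on a two-week grid: intercept jumps of 10-20 stress units
    and AR jumps of 0.15-0.35, both with random sign, on top of mild
    within-regime sinusoidal drift.
    """
    max_cps = n_epochs // min_separation - 1
    if n_cps > max_cps:
        raise ValueError(
            f"cannot place {n_cps} change points with min separation "
            f"{min_separation} in {n_epochs} epochs"
        )
    if n_cps > 0:
        # Rejection-free spacing: choose gaps then rescale.
        cuts = np.sort(rng.choice(
            np.arange(1, n_epochs // min_separation), size=n_cps, replace=False
        )) * min_separation
        jitter = rng.integers(0, min_separation // 2, size=n_cps)
        cp_epochs = [int(c + j) for c, j in zip(cuts, jitter)]
    else:
        cp_epochs = []

    regimes: list[RegimeSpec] = []
    intercept = float(rng.uniform(*intercept_range))
    ar = float(rng.uniform(*ar_range))
    for start in [0] + cp_epochs:
        regimes.append(
            RegimeSpec(
                start_epoch=start,
                intercept_base=intercept,
                ar_base=ar,
                drift_amplitude_intercept=drift_amplitude_intercept,
                drift_amplitude_ar=drift_amplitude_ar,
                drift_period=480.0,
            )
        )
        # Prepare the next regime's parameters.
        sign = -1.0 if rng.random() < 0.5 else 1.0
        intercept = float(
            np.clip(intercept + sign * rng.uniform(*intercept_jump), 15.0, 75.0)
        )
        sign = -1.0 if rng.random() < 0.5 else 1.0
        ar_new = ar + sign * rng.uniform(*ar_jump)
        lo, hi = 0.15, 1.0 - drift_amplitude_ar - 0.05
        if not lo <= ar_new <= hi:
            ar_new = ar - sign * rng.uniform(*ar_jump)
        ar = float(np.clip(ar_new, lo, hi))
    return regimes


def simulate_cohort(
    n_patients: int,
    outcome_slope: float,
    outcome_noise_sd: float,
    base_config: dict | None = None,
    seed: int = 0,
) -> tuple[list[StressSeries], pd.DataFrame, list[SimulationTruth]]:
    """Simulate a cohort of stress series with linked outcome scores.

    Each patient receives a random number of true change points; the
    session-15 score of every instrument is ``baseline + slope_i * n_cps
    + noise`` where ``slope_i`` rescales ``outcome_slope`` (given in GAD-7
    score units per change point) to the instrument's range.  A negative
    slope encodes the direction in which less change in physiological
    stress goes with more self-reported symptoms.

    Returns ``(series_list, outcome_matrix, truth_list)`` where the outcome
    matrix is a DataFrame with one row per patient and columns
    ``patient_id, n_cps, mean_stress, <inst>_pre, <inst>_s15``.
    """
    if n_patients < 3:
        raise ValueError("n_patients must be >= 3 (correlation degenerate)")
    cfg = {
        "n_days": 14,
        "epoch_minutes": 3,
        "noise_sd": 8.0,
        "missing": MissingnessSpec.realistic(),
        "max_cps": 8,
    }
    if base_config:
        cfg.update(base_config)
    rng = np.random.default_rng(seed)
    n_epochs = cfg["n_days"] * 1440 // cfg["epoch_minutes"]

    series_list: list[StressSeries] = []
    truths: list[SimulationTruth] = []
    rows: list[dict] = []
    for i in range(n_patients):
        pid = f"P{i + 1:03d}"
        max_cps = min(int(cfg["max_cps"]), n_epochs // 400 - 1)
        n_cps = int(rng.integers(0, max(max_cps, 0) + 1))
        regimes = random_regimes(n_cps, n_epochs, rng)
        series, truth = simulate_stress_series(
            regimes,
            cfg["missing"],
            n_days=cfg["n_days"],
            epoch_minutes=cfg["epoch_minutes"],
            noise_sd=cfg["noise_sd"],
            seed=rng,
            patient_id=pid,
        )
        series_list.append(series)
        truths.append(truth)
        row: dict = {
            "patient_id": pid,
            "n_cps": n_cps,
            "mean_stress": float(np.nanmean(series.values)),
        }
        for inst, (lo, hi) in INSTRUMENT_RANGES.items():
            mu, _ = _BASELINE_MOMENTS[inst]
            scale = (hi - lo) / 21.0  # slope/noise given in GAD-7 units
            pre = mu + rng.normal(0.0, outcome_noise_sd) * scale
            s15 = (
                mu
                + outcome_slope * scale * n_cps
                + rng.normal(0.0, outcome_noise_sd) * scale
            )
            row[f"{inst}_pre"] = float(np.clip(pre, lo, hi))
            row[f"{inst}_s15"] = float(np.clip(s15, lo, hi))
        rows.append(row)
    outcomes = pd.DataFrame(rows)
    return series_list, outcomes, truths
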