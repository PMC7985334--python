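"""Linking change-point counts and stress levels to questionnaire outcomes.

Per-patient correlates: the number of accepted change points in the
two-week stress series and the mean observed stress level.  Outcomes: four
self-report instruments (HSCL-11 general distress, OQ-30 treatment
outcome, GAD-7 anxiety, PHQ-9 depression) at pre-treatment and at session
15.  The analysis computes product-moment correlations at both occasions
and, for session 15, first-order partial correlations adjusting for the
same instrument's pre-treatment score (initial impairment).

Complete-case handling is listwise per instrument: a patient enters an
instrument's correlations only with scores at both occasions plus a CP
count, and that single subset is used for the pre-treatment and
session-15 correlations alike.
"""

from __future__ import annotations

import importlib.resources
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "INSTRUMENTS",
    "COMPARATIVE_SAMPLE",
    "load_outcomes",
    "case_series_outcomes",
    "complete_cases",
    "pearson_r",
    "partial_r",
    "correlation_table",
]

#: Instruments and their valid score ranges.
INSTRUMENTS: dict[str, tuple[float, float]] = {
    "hscl11": (1.0, 4.0),
    "oq30": (0.0, 4.0),
    "gad7": (0.0, 21.0),
    "phq9": (0.0, 27.0),
}

#: Reference outpatient sample (N = 377) mean (SD) per instrument, shipped
#: for report context only — no inference is run against it.
COMPARATIVE_SAMPLE: dict[str, tuple[float, float]] = {
    "hscl11": (2.20, 0.65),
    "oq30": (1.90, 0.56),
    "gad7": (11.02, 5.06),
    "phq9": (12.48, 5.73),
}

_SCORE_COLUMNS = [f"{inst}_{occ}" for inst in INSTRUMENTS for occ in ("pre", "s15")]


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    if "patient_id" not in df.columns or "n_cps" not in df.columns:
        raise ValueError("outcome table needs patient_id and n_cps columns")
    if (df["n_cps"].dropna() < 0).any():
        raise ValueError("n_cps must be >= 0")
    for inst, (lo, hi) in INSTRUMENTS.items():
        for occ in ("pre", "s15"):
            col = f"{inst}_{occ}"
            if col not in df.columns:
                raise ValueError(f"outcome table missing column {col}")
            vals = df[col].dropna()
            if ((vals < lo) | (vals > hi)).any():
                # Published case-series tables occasionally carry scores one
                # point past the nominal maximum; accept them but say so.
                warnings.warn(
                    f"{col} outside nominal range [{lo}, {hi}]",
                    UserWarning,
                    stacklevel=2,
                )
    return df


def load_outcomes(path: str | Path) -> pd.DataFrame:
    """Read a per-patient outcome table (one row per patient)."""
    df = pd.read_csv(path)
    return _validate(df)


def case_series_outcomes() -> pd.DataFrame:
    """The bundled seven-patient case-series outcome table.

    One patient (F) lacks all session-15 scores; complete-case analyses
    therefore run on six patients.
    """
    ref = importlib.resources.files("tvcpar.data") / "outcomes_case_series.csv"
    with importlib.resources.as_file(ref) as p:
        return load_outcomes(p)


def complete_cases(matrix: pd.DataFrame, instrument: str) -> pd.DataFrame:
    """Listwise subset for one instrument: pre, session-15 and CP count."""
    if instrument not in INSTRUMENTS:
        raise ValueError(f"unknown instrument {instrument!r}")
    cols = [f"{instrument}_pre", f"{instrument}_s15", "n_cps"]
    out = matrix.dropna(subset=cols)
    if len(out) < 3:
        raise ValueError(
            f"correlation undefined: only {len(out)} complete cases for "
            f"{instrument}"
        )
    return out.reset_index(drop=True)


def _as_vec(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if np.isnan(v).any():
        raise ValueError(f"{name} contains missing values")
    return v


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3)."""
    xv, yv = _as_vec(x, "x"), _as_vec(y, "y")
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    if xv.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("constant input: correlation undefined")
    return float(stats.pearsonr(xv, yv).statistic)


def partial_r(x, y, z) -> float:
    """First-order partial correlation of x and y controlling for z.

    ``r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))`` —
    equivalently the correlation of the residuals of x and y after
    regressing each on z.
    """
    xv, yv, zv = _as_vec(x, "x"), _as_vec(y, "y"), _as_vec(z, "z")
    if not (xv.size == yv.size == zv.size):
        raise ValueError("x, y, z must have equal length")
    if xv.size < 4:
        raise ValueError("need at least 4 observations")
    r_xy = pearson_r(xv, yv)
    r_xz = pearson_r(xv, zv)
    r_yz = pearson_r(yv, zv)
    denom = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom <= 0:
        raise ValueError("collinear control variable")
    return float((r_xy - r_xz * r_yz) / np.sqrt(denom))


def _r_pvalue(r: float, n: int, n_controls: int = 0) -> float:
    df = n - 2 - n_controls
    if df <= 0:
        return float("nan")
    r = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r * np.sqrt(df / (1.0 - r**2))
    return float(2.0 * stats.t.sf(abs(t), df))


def correlation_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Correlation report, one row per instrument.

    Columns per row: the complete-case n, mean/SD (sample SD, n-1
    denominator) at pre and session 15, the correlation of the CP count
    with the score at both occasions, the session-15 partial correlation
    controlling for the pre score, and — when a ``mean_stress`` column is
    present — the analogous stress-level correlations.  Two-sided
    t-distribution p-values accompany each correlation; they serve only
    to star entries at p < 0.05.
    """
    _validate(matrix)
    has_stress = "mean_stress" in matrix.columns and matrix["mean_stress"].notna().all()
    rows = []
    for inst in INSTRUMENTS:
        sub = complete_cases(matrix, inst)
        n = len(sub)
        pre = sub[f"{inst}_pre"].to_numpy(dtype=float)
        s15 = sub[f"{inst}_s15"].to_numpy(dtype=float)
        cps = sub["n_cps"].to_numpy(dtype=float)
        row: dict = {
            "instrument": inst,
            "n_used": n,
            "pre_mean": float(pre.mean()),
            "pre_sd": float(pre.std(ddof=1)),
            "s15_mean": float(s15.mean()),
            "s15_sd": float(s15.std(ddof=1)),
            "r_cps_pre": pearson_r(cps, pre) if pre.std() > 0 else float("nan"),
            "r_cps_s15": pearson_r(cps, s15),
            # controlling for a constant baseline changes nothing
            "r_partial_cps": (
                partial_r(cps, s15, pre)
                if pre.std() > 0
                else pearson_r(cps, s15)
            ),
        }
        row["p_cps_pre"] = _r_pvalue(row["r_cps_pre"], n)
        row["p_cps_s15"] = _r_pvalue(row["r_cps_s15"], n)
        row["p_partial_cps"] = _r_pvalue(row["r_partial_cps"], n, n_controls=1)
        if has_stress:
            stress = sub["mean_stress"].to_numpy(dtype=float)
            row["r_stress_pre"] = (
                pearson_r(stress, pre) if pre.std() > 0 else float("nan")
            )
            row["r_stress_s15"] = pearson_r(stress, s15)
            row["r_partial_stress"] = (
                partial_r(stress, s15, pre)
                if pre.std() > 0
                else pearson_r(stress, s15)
            )
            row["p_stress_pre"] = _r_pvalue(row["r_stress_pre"], n)
            row["p_stress_s15"] = _r_pvalue(row["r_stress_s15"], n)
            row["p_partial_stress"] = _r_pvalue(
                row["r_partial_stress"], n, n_controls=1
            )
        for key in list(row):
            if key.startswith("p_"):
                row["star" + key[1:]] = row[key] < 0.05
        rows.append(row)
    return pd.DataFrame(rows)
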