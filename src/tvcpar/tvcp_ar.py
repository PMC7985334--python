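"""Time-varying change-point AR(1) estimation and detection.

The model for a stress series :math:`y_t` on a regular epoch grid is

.. math::

    y_t = f_0(t) + f_1(t)\\, y_{t-1} + \\varepsilon_t,
    \\qquad \\varepsilon_t \\sim N(0, \\sigma^2),

where the intercept :math:`f_0` and the time-varying autoregressive
coefficient :math:`f_1` (the *inertia* of the process) are penalized cubic
regression splines in epoch time.  This captures gradual change.  Abrupt
change is captured by an augmented model with constant regime shifts
:math:`\\delta_0, \\delta_1` switching on at a candidate change point (CP):

.. math::

    y_t = f_0(t) + \\delta_0 I(t \\ge c)
          + [f_1(t) + \\delta_1 I(t \\ge c)]\\, y_{t-1} + \\varepsilon_t.

A candidate is scored by ``delta_aic = AIC(CP model) - AIC(gradual model)``;
strongly negative values favour the CP, and a CP is accepted when
``delta_aic`` falls below a threshold (default -15, chosen to keep false
positives rare).  Detection proceeds by exhaustive search over candidate
epochs followed by recursive binary segmentation: the series is split at an
accepted CP and both halves are searched again.  A greedy pruning pass then
enforces a minimum gap between CPs and a margin from the series boundaries,
since regimes with very few measurements cannot support stable estimates.

Within a search window, both models share the smoothing parameters selected
for the gradual fit (by penalized maximum likelihood, REML-type, by
default), so the AIC comparison isolates the regime shift itself.

Missing epochs enter nowhere: an AR lag pair ``(y_{t-1}, y_t)`` is usable
only when both slots are observed and grid-adjacent.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

from .ema_io import CODE_OBSERVED, StressSeries, modeling_view, wear_report

__all__ = [
    "LagPairSet",
    "TVARModel",
    "ChangePoint",
    "ChangePointSet",
    "DetectorConfig",
    "build_lag_pairs",
    "fit_tv_ar",
    "fit_cp_ar",
    "delta_aic",
    "search_best_cp",
    "detect_change_points",
    "prune_change_points",
    "final_inertia_model",
    "inertia_frame",
]

_RSS_FLOOR = 1e-10  # per-observation floor keeping the Gaussian loglik finite


@dataclasses.dataclass(frozen=True)
class DetectorConfig:
    """Tuning parameters of the change-point detector.

    ``threshold`` is in AIC units (negative: the CP model must beat the
    gradual model by at least this much).  ``min_segment`` counts usable
    lag pairs per regime; ``min_gap`` and ``boundary_margin`` are in
    epochs and default to ``min_segment``.  ``candidate_stride`` > 1
    thins the candidate grid for speed.
    """

    threshold: float = -15.0
    min_segment: int = 50
    min_gap: int | None = None
    boundary_margin: int | None = None
    candidate_stride: int = 1
    max_depth: int = 12
    basis_dim: int = 10
    smoothing: str = "penalized_ml"

    def __post_init__(self) -> None:
        if self.threshold >= 0:
            raise ValueError("threshold must be negative")
        if self.min_segment < 2:
            raise ValueError("min_segment must be >= 2")
        if self.candidate_stride < 1:
            raise ValueError("candidate_stride must be >= 1")
        if self.basis_dim < 4:
            raise ValueError("basis_dim must be >= 4 (cubic splines)")
        if self.smoothing not in {"penalized_ml", "cross_validation"}:
            raise ValueError(f"unknown smoothing method {self.smoothing!r}")
        if self.min_gap is None:
            object.__setattr__(self, "min_gap", self.min_segment)
        if self.boundary_margin is None:
            object.__setattr__(self, "boundary_margin", self.min_segment)


@dataclasses.dataclass
class LagPairSet:
    """Complete adjacent lag pairs ``(y_{t-1}, y_t)`` of a series.

    ``t_index`` is the grid index of the response slot; ``segment_id``
    numbers maximal runs of consecutive pairs (a gap in the series starts
    a new segment).
    """

    t_index: np.ndarray
    y_prev: np.ndarray
    y_curr: np.ndarray
    segment_id: np.ndarray

    def __len__(self) -> int:
        return int(self.t_index.size)

    def subset(self, mask: np.ndarray) -> "LagPairSet":
        return LagPairSet(
            t_index=self.t_index[mask],
            y_prev=self.y_prev[mask],
            y_curr=self.y_curr[mask],
            segment_id=self.segment_id[mask],
        )

    def window(self, start: int, end: int) -> "LagPairSet":
        """Pairs whose response epoch lies in the half-open [start, end)."""
        return self.subset((self.t_index >= start) & (self.t_index < end))


def build_lag_pairs(series: StressSeries, min_pairs: int = 2) -> LagPairSet:
    """Extract usable AR lag pairs from a regularized series.

    A pair exists for every observed slot whose immediate predecessor slot
    is also observed; pairs spanning any kind of missing slot are excluded
    (no imputation).
    """
    if not series.is_regular:
        raise ValueError("build_lag_pairs requires a regularized grid")
    obs = series.codes == CODE_OBSERVED
    ok = obs[1:] & obs[:-1]
    t = np.flatnonzero(ok) + 1
    if t.size < min_pairs:
        raise ValueError(
            f"series too short or too gappy: {t.size} usable lag pairs "
            f"(need >= {min_pairs})"
        )
    seg = np.concatenate([[0], np.cumsum(np.diff(t) > 1)])
    return LagPairSet(
        t_index=t.astype(np.int64),
        y_prev=series.values[t - 1].astype(float),
        y_curr=series.values[t].astype(float),
        segment_id=seg.astype(np.int64),
    )


# ---------------------------------------------------------------------------
# Penalized spline machinery
# ---------------------------------------------------------------------------


def _spline_knots(t_min: float, t_max: float, basis_dim: int) -> np.ndarray:
    if t_max <= t_min:
        t_max = t_min + 1.0
    inner = np.linspace(t_min, t_max, basis_dim - 2)[1:-1]
    return np.concatenate([[t_min] * 4, inner, [t_max] * 4])


def _basis_matrix(t: np.ndarray, knots: np.ndarray) -> np.ndarray:
    x = np.clip(np.asarray(t, dtype=float), knots[0], knots[-1])
    return BSpline.design_matrix(x, knots, 3).toarray()


def _difference_penalty(basis_dim: int) -> np.ndarray:
    d = np.diff(np.eye(basis_dim), n=2, axis=0)
    return d.T @ d


class _FitState:
    """Internal numerical state of a penalized fit, reused by the CP scan."""

    __slots__ = (
        "t", "y_prev", "y", "X", "XtX", "Xty", "yty", "S_blocks", "ranks",
        "null_dim", "knots", "basis_dim", "loglam", "S_lam", "chol", "beta",
        "resid", "rss", "edf", "n", "p", "intercept_only",
    )


def _assemble(state: _FitState, loglam: np.ndarray):
    lam = np.exp(np.clip(loglam, -12.0, 25.0))
    S_lam = sum(l * S for l, S in zip(lam, state.S_blocks))
    M = state.XtX + S_lam
    jitter = 0.0
    scale = np.trace(state.XtX) / state.p
    for _ in range(6):
        try:
            chol = cho_factor(M + jitter * np.eye(state.p), lower=True)
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-10 * scale)
    else:  # pragma: no cover - pathological input
        raise np.linalg.LinAlgError("normal equations not positive definite")
    beta = cho_solve(chol, state.Xty)
    rss = float(state.yty - 2.0 * beta @ state.Xty + beta @ (state.XtX @ beta))
    rss = max(rss, state.n * _RSS_FLOOR)
    return lam, S_lam, chol, beta, rss


def _smoothing_score(state: _FitState, loglam: np.ndarray, method: str) -> float:
    try:
        lam, S_lam, chol, beta, rss = _assemble(state, loglam)
    except np.linalg.LinAlgError:
        return np.inf
    penalty = float(beta @ (S_lam @ beta))
    L = chol[0]
    logdet_M = 2.0 * float(np.sum(np.log(np.diag(L))))
    if method == "penalized_ml":
        # Gaussian REML-type marginal likelihood, sigma^2 profiled out.
        logdet_S = float(
            sum(r * ll for r, ll in zip(state.ranks, np.clip(loglam, -12.0, 25.0)))
        )
        return (
            0.5 * (state.n - state.null_dim) * np.log(rss + penalty)
            + 0.5 * (logdet_M - logdet_S)
        )
    # GCV
    edf = float(np.trace(cho_solve(chol, state.XtX)))
    denom = max(state.n - edf, 1e-6)
    return state.n * rss / denom**2


def _select_smoothing(state: _FitState, method: str) -> np.ndarray:
    k = len(state.S_blocks)
    grid = np.array([-2.0, 2.0, 6.0, 10.0, 14.0])
    best, best_val = None, np.inf
    mesh = np.meshgrid(*([grid] * k))
    for point in zip(*[m.ravel() for m in mesh]):
        val = _smoothing_score(state, np.array(point), method)
        if val < best_val:
            best, best_val = np.array(point), val
    if best is None or not np.isfinite(best_val):
        raise RuntimeError(
            "smoothing selection failed: no finite criterion value on the "
            f"initial grid (n={state.n}, basis_dim={state.basis_dim})"
        )
    res = optimize.minimize(
        lambda ll: _smoothing_score(state, ll, method),
        best,
        method="Nelder-Mead",
        options={"xatol": 0.05, "fatol": 1e-4, "maxiter": 200},
    )
    return res.x if np.isfinite(res.fun) else best


def _gaussian_loglik(rss: float, n: int) -> float:
    return -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)


@dataclasses.dataclass
class TVARModel:
    """A fitted time-varying AR(1) (optionally with one regime shift).

    ``intercept_curve`` and ``ar_curve`` are evaluated at every lag pair's
    response epoch; ``ar_curve`` is the time-varying inertia.  ``aic`` is
    ``-2 loglik + 2 edf`` with ``edf`` the trace of the penalized
    smoother's influence matrix.
    """

    t_index: np.ndarray
    intercept_curve: np.ndarray
    ar_curve: np.ndarray
    edf: float
    loglik: float
    aic: float
    residual_sd: float
    basis_dim: int
    smoothing: str
    lambdas: np.ndarray
    cp_epoch: int | None = None
    delta_intercept: float | None = None
    delta_ar: float | None = None
    rank_fallback: bool = False
    _state: _FitState | None = dataclasses.field(
        default=None, repr=False, compare=False
    )
    _coef: np.ndarray | None = dataclasses.field(
        default=None, repr=False, compare=False
    )

    @property
    def n_pairs(self) -> int:
        return int(self.t_index.size)

    def curves_at(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate (intercept, inertia) curves at arbitrary epochs."""
        st = self._state
        if st is None:
            raise ValueError("model carries no basis state")
        B = _basis_matrix(np.asarray(t, dtype=float), st.knots)
        K = st.basis_dim
        if st.intercept_only:
            f0 = B @ self._coef[:K]
            f1 = np.zeros_like(f0)
        else:
            f0 = B @ self._coef[:K]
            f1 = B @ self._coef[K : 2 * K]
        if self.cp_epoch is not None:
            step = (np.asarray(t) >= self.cp_epoch).astype(float)
            f0 = f0 + self.delta_intercept * step
            f1 = f1 + self.delta_ar * step
        return f0, f1


def _prepare_state(
    t: np.ndarray,
    y_prev: np.ndarray,
    y: np.ndarray,
    basis_dim: int,
    t_range: tuple[float, float] | None,
    intercept_only: bool,
) -> _FitState:
    st = _FitState()
    st.t = np.asarray(t, dtype=float)
    st.y_prev = np.asarray(y_prev, dtype=float)
    st.y = np.asarray(y, dtype=float)
    st.n = st.y.size
    st.basis_dim = basis_dim
    st.intercept_only = intercept_only
    lo, hi = t_range if t_range is not None else (st.t[0], st.t[-1])
    st.knots = _spline_knots(float(lo), float(hi), basis_dim)
    B = _basis_matrix(st.t, st.knots)
    S = _difference_penalty(basis_dim)
    if intercept_only:
        st.X = B
        st.S_blocks = [S]
    else:
        st.X = np.hstack([B, B * st.y_prev[:, None]])
        zero = np.zeros_like(S)
        st.S_blocks = [
            np.block([[S, zero], [zero, zero]]),
            np.block([[zero, zero], [zero, S]]),
        ]
    st.p = st.X.shape[1]
    st.ranks = [basis_dim - 2] * len(st.S_blocks)
    st.null_dim = 2 * len(st.S_blocks)
    st.XtX = st.X.T @ st.X
    st.Xty = st.X.T @ st.y
    st.yty = float(st.y @ st.y)
    return st


def fit_tv_ar(
    pairs: LagPairSet,
    config: DetectorConfig | None = None,
    *,
    t_range: tuple[float, float] | None = None,
) -> TVARModel:
    """Fit the gradual-change model ``y_t = f0(t) + f1(t) y_{t-1} + e_t``.

    Both smooths are penalized cubic regression splines with
    ``config.basis_dim`` basis functions on evenly spaced knots over the
    observed epoch range; smoothing parameters are selected by the
    configured criterion (penalized ML by default, GCV as the
    alternative).

    Falls back to an intercept-only smooth with a warning when ``y_prev``
    is (numerically) constant, in which case the inertia curve is zero.
    """
    config = config or DetectorConfig()
    n = len(pairs)
    if n < config.min_segment:
        raise ValueError(f"{n} pairs < min_segment={config.min_segment}")
    intercept_only = float(np.std(pairs.y_prev)) < 1e-9
    if intercept_only:
        warnings.warn(
            "y_prev is constant; falling back to an intercept-only smooth",
            RuntimeWarning,
            stacklevel=2,
        )
    st = _prepare_state(
        pairs.t_index, pairs.y_prev, pairs.y_curr, config.basis_dim,
        t_range, intercept_only,
    )
    loglam = _select_smoothing(st, config.smoothing)
    lam, S_lam, chol, beta, rss = _assemble(st, loglam)
    st.loglam = loglam
    st.S_lam = S_lam
    st.chol = chol
    st.beta = beta
    st.rss = rss
    st.resid = st.y - st.X @ beta
    edf = float(np.trace(cho_solve(chol, st.XtX)))
    st.edf = edf
    loglik = _gaussian_loglik(rss, n)
    aic = -2.0 * loglik + 2.0 * edf
    K = config.basis_dim
    B = st.X[:, :K] if not intercept_only else st.X
    f0 = B @ beta[:K]
    f1 = (
        np.zeros(n)
        if intercept_only
        else _basis_matrix(st.t, st.knots) @ beta[K : 2 * K]
    )
    return TVARModel(
        t_index=pairs.t_index.copy(),
        intercept_curve=f0,
        ar_curve=f1,
        edf=edf,
        loglik=loglik,
        aic=aic,
        residual_sd=float(np.sqrt(rss / max(n - edf, 1.0))),
        basis_dim=K,
        smoothing=config.smoothing,
        lambdas=lam,
        rank_fallback=intercept_only,
        _state=st,
        _coef=beta,
    )


def _split_counts(pairs: LagPairSet, cp_epoch: int) -> tuple[int, int]:
    k = int(np.searchsorted(pairs.t_index, cp_epoch))
    return k, len(pairs) - k


def fit_cp_ar(
    pairs: LagPairSet,
    cp_epoch: int,
    config: DetectorConfig | None = None,
    gradual: TVARModel | None = None,
) -> TVARModel:
    """Fit the gradual model augmented with a regime shift at ``cp_epoch``.

    Adds two unpenalized columns — a step in the intercept and a step in
    the AR coefficient — while keeping the smoothing parameters selected
    for the gradual model on the same pairs, so the AIC comparison
    isolates the shift.  The effective degrees of freedom include the two
    extra parameters (exactly, via the influence-matrix trace).
    """
    config = config or DetectorConfig()
    left, right = _split_counts(pairs, cp_epoch)
    if left < config.min_segment or right < config.min_segment:
        raise ValueError(
            f"regime too small at cp={cp_epoch}: {left} / {right} pairs "
            f"(need >= {config.min_segment} each; a regime cannot consist "
            "of a handful of measurements)"
        )
    if gradual is None:
        gradual = fit_tv_ar(pairs, config)
    st = gradual._state
    if st is None or st.intercept_only:
        raise ValueError("cp model requires a full gradual fit (no fallback)")
    n, p = st.n, st.p
    step = (st.t >= cp_epoch).astype(float)
    U = np.column_stack([step, step * st.y_prev])
    # Rank-2 Schur-complement update of the factorized gradual system:
    # minimize ||y - X b - U g||^2 + b' S_lam b with g unpenalized.
    W = st.X.T @ U
    C = cho_solve(st.chol, W)
    Sc = U.T @ U - W.T @ C
    det = Sc[0, 0] * Sc[1, 1] - Sc[0, 1] * Sc[1, 0]
    if det <= 1e-10 * max(Sc[0, 0] * Sc[1, 1], 1e-300):
        raise ValueError(
            f"singular CP design at cp={cp_epoch} (collinear regime shift)"
        )
    G = np.linalg.inv(Sc)
    gamma = G @ (U.T @ st.resid)
    beta = st.beta - C @ gamma
    resid = st.y - st.X @ beta - U @ gamma
    rss = max(float(resid @ resid), n * _RSS_FLOOR)
    edf = float(st.edf + 2.0 - np.trace(G @ (C.T @ (st.S_lam @ C))))
    loglik = _gaussian_loglik(rss, n)
    aic = -2.0 * loglik + 2.0 * edf
    K = config.basis_dim
    B = _basis_matrix(st.t, st.knots)
    f0 = B @ beta[:K] + gamma[0] * step
    f1 = B @ beta[K : 2 * K] + gamma[1] * step
    return TVARModel(
        t_index=pairs.t_index.copy(),
        intercept_curve=f0,
        ar_curve=f1,
        edf=edf,
        loglik=loglik,
        aic=aic,
        residual_sd=float(np.sqrt(rss / max(n - edf, 1.0))),
        basis_dim=K,
        smoothing=config.smoothing,
        lambdas=gradual.lambdas,
        cp_epoch=int(cp_epoch),
        delta_intercept=float(gamma[0]),
        delta_ar=float(gamma[1]),
        _state=st,
        _coef=beta[: 2 * K],
    )


def delta_aic(
    pairs: LagPairSet,
    cp_epoch: int,
    config: DetectorConfig | None = None,
    gradual: TVARModel | None = None,
) -> float:
    """``AIC(CP model) - AIC(gradual model)``; negative favours the CP."""
    config = config or DetectorConfig()
    if gradual is None:
        gradual = fit_tv_ar(pairs, config)
    cp_model = fit_cp_ar(pairs, cp_epoch, config, gradual=gradual)
    return cp_model.aic - gradual.aic


# ---------------------------------------------------------------------------
# Vectorized candidate scan
# ---------------------------------------------------------------------------


def _scan_deltas(gradual: TVARModel, split_idx: np.ndarray) -> np.ndarray:
    """delta AIC for all candidate split positions in one vectorized pass.

    ``split_idx[j] = k`` means pairs ``k..n-1`` form the right regime.
    Uses rank-2 Schur-complement updates of the penalized normal
    equations; algebraically identical to :func:`fit_cp_ar` with the same
    shared smoothing parameters.
    """
    st = gradual._state
    n, p = st.n, st.p
    X, yp, r = st.X, st.y_prev, st.resid
    # Suffix sums: entry k = sum over rows k..n-1.
    sufX = np.cumsum(X[::-1], axis=0)[::-1]          # (n, p)
    sufXyp = np.cumsum((X * yp[:, None])[::-1], axis=0)[::-1]
    suf1 = np.arange(n, 0, -1, dtype=float)
    sufyp = np.cumsum(yp[::-1])[::-1]
    sufyp2 = np.cumsum((yp * yp)[::-1])[::-1]
    sufr = np.cumsum(r[::-1])[::-1]
    sufryp = np.cumsum((r * yp)[::-1])[::-1]

    k = split_idx
    m = k.size
    W = np.empty((m, p, 2))
    W[:, :, 0] = sufX[k]
    W[:, :, 1] = sufXyp[k]
    UtU = np.empty((m, 2, 2))
    UtU[:, 0, 0] = suf1[k]
    UtU[:, 0, 1] = UtU[:, 1, 0] = sufyp[k]
    UtU[:, 1, 1] = sufyp2[k]
    Utr = np.stack([sufr[k], sufryp[k]], axis=1)  # (m, 2)

    C = cho_solve(st.chol, W.transpose(1, 0, 2).reshape(p, 2 * m)).reshape(
        p, m, 2
    ).transpose(1, 0, 2)                            # (m, p, 2)
    Sc = UtU - np.einsum("mpi,mpj->mij", W, C)
    SlamC = np.einsum("pq,mqi->mpi", st.S_lam, C)
    CtSlamC = np.einsum("mpi,mpj->mij", C, SlamC)

    det = Sc[:, 0, 0] * Sc[:, 1, 1] - Sc[:, 0, 1] * Sc[:, 1, 0]
    scale = np.maximum(Sc[:, 0, 0] * Sc[:, 1, 1], 1e-300)
    valid = det > 1e-10 * scale
    deltas = np.full(m, np.inf)
    if not valid.any():
        return deltas

    inv = np.empty((m, 2, 2))
    inv[:, 0, 0] = Sc[:, 1, 1]
    inv[:, 1, 1] = Sc[:, 0, 0]
    inv[:, 0, 1] = -Sc[:, 0, 1]
    inv[:, 1, 0] = -Sc[:, 1, 0]
    inv /= np.where(valid, det, 1.0)[:, None, None]
    gamma = np.einsum("mij,mj->mi", inv, Utr)

    a = st.X.T @ r                                   # = S_lam @ beta
    Cta = np.einsum("mpi,p->mi", C, a)
    lin = np.einsum("mi,mi->m", gamma, Utr - Cta)
    Q = Sc - CtSlamC
    quad = np.einsum("mi,mij,mj->m", gamma, Q, gamma)
    rss_new = np.maximum(st.rss - 2.0 * lin + quad, n * _RSS_FLOOR)

    tr_corr = np.einsum("mij,mji->m", inv, CtSlamC)
    edf_new = st.edf + 2.0 - tr_corr
    aic_new = n * np.log(2.0 * np.pi * rss_new / n) + n + 2.0 * edf_new
    deltas_valid = aic_new - gradual.aic
    deltas[valid] = deltas_valid[valid]
    return deltas


def search_best_cp(
    pairs: LagPairSet,
    window: tuple[int, int],
    config: DetectorConfig | None = None,
    gradual: TVARModel | None = None,
) -> tuple[int, float] | None:
    """Exhaustive CP search over a window of the epoch grid.

    Candidate epochs are the observed response epochs in the half-open
    window (thinned by ``candidate_stride``) whose left/right parts each
    hold at least ``min_segment`` pairs and which keep
    ``boundary_margin`` epochs to the window edges.  Returns the
    ``(epoch, delta_aic)`` minimizing ``delta_aic``, or ``None`` if no
    candidate is admissible.
    """
    config = config or DetectorConfig()
    w0, w1 = int(window[0]), int(window[1])
    sub = pairs.window(w0, w1)
    n = len(sub)
    if n < 2 * config.min_segment + 1:
        return None
    if gradual is None:
        if float(np.std(sub.y_prev)) < 1e-9:
            warnings.warn(
                f"window [{w0}, {w1}): degenerate (constant) series; "
                "skipping CP search",
                RuntimeWarning,
                stacklevel=2,
            )
            return None
        gradual = fit_tv_ar(sub, config)
    if gradual.rank_fallback:
        return None

    t = sub.t_index
    k = np.arange(1, n)
    c = t[k]
    admissible = (
        (k >= config.min_segment)
        & (n - k >= config.min_segment)
        & (c - w0 >= config.boundary_margin)
        & (w1 - c >= config.boundary_margin)
        & ((c - w0) % config.candidate_stride == 0)
    )
    k = k[admissible]
    if k.size == 0:
        return None
    deltas = _scan_deltas(gradual, k)
    finite = np.isfinite(deltas)
    if not finite.any():
        return None
    j = int(np.argmin(np.where(finite, deltas, np.inf)))
    epoch = int(t[k[j]])
    # Re-evaluate the winner through the per-candidate path: the vectorized
    # scan is exact up to accumulated rounding, the dense solve is not.
    best = fit_cp_ar(sub, epoch, config, gradual=gradual).aic - gradual.aic
    return epoch, float(best)


@dataclasses.dataclass
class ChangePoint:
    """An accepted or candidate change point."""

    epoch: int
    timestamp: pd.Timestamp
    delta_aic: float
    exclusion_reason: str | None = None

    def to_dict(self) -> dict:
        d = {
            "epoch": int(self.epoch),
            "timestamp": self.timestamp.isoformat(),
            "delta_aic": float(self.delta_aic),
        }
        if self.exclusion_reason:
            d["exclusion_reason"] = self.exclusion_reason
        return d


@dataclasses.dataclass
class ChangePointSet:
    """Accepted CPs, the regime partition they induce, and exclusions."""

    cps: list[ChangePoint]
    regimes: list[tuple[int, int]]
    excluded: list[ChangePoint]
    window: tuple[int, int]

    @property
    def n_cps(self) -> int:
        return len(self.cps)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "window": [int(self.window[0]), int(self.window[1])],
                "change_points": [cp.to_dict() for cp in self.cps],
                "regimes": [[int(a), int(b)] for a, b in self.regimes],
                "excluded": [cp.to_dict() for cp in self.excluded],
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def prune_change_points(
    cps: list[ChangePoint],
    config: DetectorConfig | None = None,
    series_window: tuple[int, int] | None = None,
) -> tuple[list[ChangePoint], list[ChangePoint]]:
    """Greedy pruning of clustered or boundary-adjacent CPs.

    CPs are processed by ascending ``delta_aic`` (strongest evidence
    first); one is accepted iff it lies at least ``min_gap`` epochs from
    every already-accepted CP and at least ``boundary_margin`` epochs
    from both series ends.  Rejected CPs carry the reason ``"boundary"``
    or ``"too_close"``.
    """
    config = config or DetectorConfig()
    if series_window is None:
        raise ValueError("series_window (start, end) is required")
    w0, w1 = series_window
    accepted: list[ChangePoint] = []
    excluded: list[ChangePoint] = []
    for cp in sorted(cps, key=lambda c: (c.delta_aic, c.epoch)):
        if cp.epoch - w0 < config.boundary_margin or w1 - cp.epoch < config.boundary_margin:
            excluded.append(dataclasses.replace(cp, exclusion_reason="boundary"))
            continue
        if any(abs(cp.epoch - a.epoch) < config.min_gap for a in accepted):
            excluded.append(dataclasses.replace(cp, exclusion_reason="too_close"))
            continue
        accepted.append(cp)
    accepted.sort(key=lambda c: c.epoch)
    excluded.sort(key=lambda c: c.epoch)
    return accepted, excluded


def _timestamp_at(series: StressSeries, epoch: int) -> pd.Timestamp:
    return series.epoch_start + pd.Timedelta(minutes=epoch * series.epoch_minutes)


def detect_change_points(
    series: StressSeries, config: DetectorConfig | None = None
) -> ChangePointSet:
    """Recursive binary segmentation with AIC-threshold acceptance.

    Runs :func:`search_best_cp` on the full window; when the best
    candidate's ``delta_aic`` beats the threshold the series is split at
    the CP and both halves are searched again, up to ``max_depth``.  The
    collected CPs then pass through :func:`prune_change_points`.

    Requires a wear-time-suitable series (wear fraction > 0.5).  The
    detector is fully deterministic.
    """
    config = config or DetectorConfig()
    report = wear_report(series)
    if not report.suitable:
        raise ValueError(
            f"series unsuitable: wear_fraction={report.wear_fraction:.3f} "
            "(need > 0.5)"
        )
    view = modeling_view(series)
    pairs = build_lag_pairs(view, min_pairs=2 * config.min_segment + 1)
    full = (0, len(series))

    obs = view.values[np.isfinite(view.values)]
    if float(np.std(obs)) < 1e-9:
        warnings.warn(
            "constant series: degenerate fit, no change points detectable",
            RuntimeWarning,
            stacklevel=2,
        )
        return ChangePointSet(cps=[], regimes=[full], excluded=[], window=full)

    found: list[ChangePoint] = []
    stack: list[tuple[int, int, int]] = [(full[0], full[1], 0)]
    while stack:
        w0, w1, depth = stack.pop()
        res = search_best_cp(pairs, (w0, w1), config)
        if res is None:
            continue
        epoch, d_aic = res
        if d_aic < config.threshold:
            found.append(
                ChangePoint(
                    epoch=epoch,
                    timestamp=_timestamp_at(series, epoch),
                    delta_aic=d_aic,
                )
            )
            if depth + 1 <= config.max_depth:
                stack.append((w0, epoch, depth + 1))
                stack.append((epoch, w1, depth + 1))

    accepted, excluded = prune_change_points(found, config, series_window=full)
    boundaries = [full[0]] + [cp.epoch for cp in accepted] + [full[1]]
    regimes = list(zip(boundaries[:-1], boundaries[1:]))
    return ChangePointSet(
        cps=accepted, regimes=regimes, excluded=excluded, window=full
    )


def final_inertia_model(
    series: StressSeries,
    cpset: ChangePointSet,
    config: DetectorConfig | None = None,
) -> list[TVARModel]:
    """Refit the gradual model independently within each regime.

    The concatenation of the per-regime inertia curves ``f1(t)`` has jump
    discontinuities at the accepted CPs.  Inertia values above 1 are
    flagged with a warning, not clamped: they occur around change points
    when residual non-stationarity leaks into the local estimate.
    """
    config = config or DetectorConfig()
    view = modeling_view(series)
    pairs = build_lag_pairs(view)
    models: list[TVARModel] = []
    for start, end in cpset.regimes:
        sub = pairs.window(start, end)
        if len(sub) < config.min_segment:
            raise ValueError(
                f"regime [{start}, {end}) has only {len(sub)} usable pairs "
                f"(need >= {config.min_segment})"
            )
        models.append(fit_tv_ar(sub, config, t_range=(start, end - 1)))
    if any(np.any(m.ar_curve > 1.0) for m in models):
        warnings.warn(
            "inertia curve exceeds 1 in at least one regime "
            "(local non-stationarity, typically near change points)",
            RuntimeWarning,
            stacklevel=2,
        )
    return models


def inertia_frame(
    series: StressSeries, models: list[TVARModel], cpset: ChangePointSet
) -> pd.DataFrame:
    """Tidy per-epoch inertia table: epoch, timestamp, f0, f1, regime, flag."""
    frames = []
    for rid, model in enumerate(models):
        ts = [
            _timestamp_at(series, int(e)) for e in model.t_index
        ]
        frames.append(
            pd.DataFrame(
                {
                    "epoch": model.t_index,
                    "timestamp": ts,
                    "intercept": model.intercept_curve,
                    "inertia": model.ar_curve,
                    "regime_id": rid,
                    "flag_gt1": model.ar_curve > 1.0,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
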