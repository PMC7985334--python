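"""Change-point search, recursive segmentation and pruning."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from tvcpar.ema_io import modeling_view
from tvcpar.synthetic_data import RegimeSpec, simulate_stress_series
from tvcpar.tvcp_ar import (
    ChangePoint,
    DetectorConfig,
    build_lag_pairs,
    delta_aic,
    detect_change_points,
    final_inertia_model,
    fit_tv_ar,
    inertia_frame,
    prune_change_points,
    search_best_cp,
)

from conftest import NO_MISSING, make_series, ols_ar1, truncate

CFG = DetectorConfig()


def _cp(epoch, d):
    return ChangePoint(epoch=epoch, timestamp=pd.Timestamp("2020-01-06", tz="UTC"),
                       delta_aic=d)


class TestSearchBestCp:
    def test_stride_one_matches_exhaustive_brute_force(self):
        cfg = DetectorConfig(min_segment=30)
        s, _ = simulate_stress_series(
            [RegimeSpec(0, 20.0, 0.4), RegimeSpec(150, 12.0, 0.7)],
            NO_MISSING, n_days=1, noise_sd=4.0, seed=31,
        )
        s = truncate(s, 300)
        pairs = build_lag_pairs(modeling_view(s))
        res = search_best_cp(pairs, (0, 300), cfg)
        assert res is not None
        # Brute force: evaluate delta_aic at every admissible response epoch.
        g = fit_tv_ar(pairs, cfg)
        best = (np.inf, None)
        t = pairs.t_index
        for k in range(1, len(pairs)):
            c = int(t[k])
            if (
                k >= cfg.min_segment
                and len(pairs) - k >= cfg.min_segment
                and c >= cfg.boundary_margin
                and 300 - c >= cfg.boundary_margin
            ):
                d = delta_aic(pairs, c, cfg, gradual=g)
                if d < best[0]:
                    best = (d, c)
        assert res[0] == best[1]
        assert res[1] == pytest.approx(best[0], abs=1e-6)

    def test_strong_cp_located(self, step_series):
        pairs = build_lag_pairs(modeling_view(step_series))
        epoch, d = search_best_cp(pairs, (0, 6000), CFG)
        assert abs(epoch - 3000) <= 50
        assert d < -15

    def test_coarse_stride_approximates_exhaustive(self, step_series):
        pairs = build_lag_pairs(modeling_view(step_series))
        exact = search_best_cp(pairs, (0, 6000), CFG)
        coarse = search_best_cp(
            pairs, (0, 6000), dataclasses.replace(CFG, candidate_stride=10)
        )
        assert abs(coarse[0] - exact[0]) <= 10
        assert coarse[1] <= exact[1] + 25.0

    def test_window_too_short_returns_none(self, stationary_pairs):
        assert search_best_cp(stationary_pairs, (0, 100), CFG) is None


class TestPrune:
    def test_weaker_of_close_pair_excluded(self):
        acc, exc = prune_change_points(
            [_cp(1000, -40.0), _cp(1005, -20.0)], CFG, series_window=(0, 2000)
        )
        assert [c.epoch for c in acc] == [1000]
        assert exc[0].epoch == 1005 and exc[0].exclusion_reason == "too_close"

    def test_boundary_cp_excluded(self):
        acc, exc = prune_change_points(
            [_cp(3, -40.0)], CFG, series_window=(0, 2000)
        )
        assert not acc
        assert exc[0].exclusion_reason == "boundary"

    def test_cluster_of_five_reduced_to_one(self):
        cluster = [_cp(1000 + 8 * i, -20.0 - i) for i in range(5)]
        acc, exc = prune_change_points(cluster, CFG, series_window=(0, 2000))
        assert len(acc) == 1 and len(exc) == 4
        assert acc[0].delta_aic == min(c.delta_aic for c in cluster)

    def test_far_apart_cps_all_kept(self):
        cps = [_cp(500, -20.0), _cp(1000, -30.0), _cp(1500, -25.0)]
        acc, exc = prune_change_points(cps, CFG, series_window=(0, 2000))
        assert len(acc) == 3 and not exc


class TestDetect:
    def test_two_well_separated_cps_recovered(self):
        regs = [
            RegimeSpec(0, 26.0, 0.3),
            RegimeSpec(2000, 14.0, 0.8),
            RegimeSpec(4000, 30.0, 0.45),
        ]
        s, _ = simulate_stress_series(regs, NO_MISSING, n_days=13,
                                      noise_sd=4.0, seed=37)
        cs = detect_change_points(truncate(s, 6000), CFG)
        eps = [cp.epoch for cp in cs.cps]
        assert min(abs(e - 2000) for e in eps) <= 50
        assert min(abs(e - 4000) for e in eps) <= 50
        assert all(cp.delta_aic < CFG.threshold for cp in cs.cps)
        # regimes partition the window
        assert cs.regimes[0][0] == 0 and cs.regimes[-1][1] == 6000
        for (a0, b0), (a1, b1) in zip(cs.regimes, cs.regimes[1:]):
            assert b0 == a1

    def test_deterministic(self, stationary_series):
        a = detect_change_points(stationary_series, CFG)
        b = detect_change_points(stationary_series, CFG)
        assert a.to_json() == b.to_json()

    def test_constant_series_warns_and_finds_nothing(self):
        s = make_series(np.full(2000, 42.0))
        with pytest.warns(RuntimeWarning, match="constant"):
            cs = detect_change_points(s, CFG)
        assert cs.n_cps == 0 and cs.regimes == [(0, 2000)]

    def test_unsuitable_series_rejected(self):
        values = np.concatenate([np.linspace(30, 50, 300),
                                 np.full(700, np.nan)])
        with pytest.raises(ValueError, match="wear_fraction"):
            detect_change_points(make_series(values), CFG)


class TestFinalInertiaModel:
    def test_single_regime_reduces_to_plain_fit(self, stationary_series):
        cs = detect_change_points(stationary_series, CFG)
        assert cs.n_cps == 0
        models = final_inertia_model(stationary_series, cs, CFG)
        pairs = build_lag_pairs(modeling_view(stationary_series))
        direct = fit_tv_ar(pairs, CFG, t_range=(0, 1999))
        assert len(models) == 1
        assert models[0].aic == pytest.approx(direct.aic, abs=1e-6)
        np.testing.assert_allclose(models[0].ar_curve, direct.ar_curve,
                                   atol=1e-8)

    def test_two_regime_means_match_per_regime_ols(self, step_series):
        cs = detect_change_points(step_series, CFG)
        models = final_inertia_model(step_series, cs, CFG)
        pairs = build_lag_pairs(modeling_view(step_series))
        for (a, b), m in zip(cs.regimes, models):
            sub = pairs.window(a, b)
            _, phi = ols_ar1(sub.y_prev, sub.y_curr)
            assert m.ar_curve.mean() == pytest.approx(phi, abs=0.07)

    def test_inertia_above_one_flagged(self):
        # Near-unit-root data pushes the local estimate above 1 somewhere.
        rng = np.random.default_rng(3)
        n = 600
        x = np.empty(n)
        xp = 50.0
        for t in range(n):
            phi = 0.99 if t > n // 2 else 0.3
            xp = 50.0 * (1 - phi) + phi * xp + rng.normal(0, 6.0)
            x[t] = xp
        s = make_series(np.clip(np.rint(x), 0, 100))
        from tvcpar.tvcp_ar import ChangePointSet

        cs = ChangePointSet(cps=[], regimes=[(0, n)], excluded=[],
                            window=(0, n))
        models = final_inertia_model(s, cs, CFG)
        frame = inertia_frame(s, models, cs)
        if frame["flag_gt1"].any():
            assert frame.loc[frame["flag_gt1"], "inertia"].min() > 1.0
        assert set(frame.columns) >= {"epoch", "timestamp", "intercept",
                                      "inertia", "regime_id", "flag_gt1"}
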