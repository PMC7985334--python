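# tvcpar

Time-varying change-point AR(1) modelling of wearable EMA stress series.

Wrist-worn trackers report a heart-rate-variability-derived **stress level**
in [0, 100] for every 3-minute epoch — 6,720 values over a two-week wear
period. For patients in cognitive-behavioural therapy, the *inertia* of this
signal (its resistance to change, operationalized as the lag-1
autoregressive coefficient) is a candidate marker of change processes:
inertia can drift gradually and it can shift abruptly. `tvcpar` is for
researchers in psychotherapy process research and affect dynamics who want
to estimate both kinds of change from such series and relate them to
treatment outcomes.

## The model

For a stress series \(y_t\) on a regular epoch grid,

\[ y_t = f_0(t) + f_1(t)\, y_{t-1} + \varepsilon_t, \qquad
   \varepsilon_t \sim N(0, \sigma^2), \]

with \(f_0\) (intercept) and \(f_1\) (time-varying inertia) penalized cubic
regression splines — the *gradual-change* model. A candidate **change point
(CP)** at epoch \(c\) augments it with constant regime shifts
\(\delta_0, \delta_1\):

\[ y_t = f_0(t) + \delta_0 I(t \ge c)
       + [f_1(t) + \delta_1 I(t \ge c)]\, y_{t-1} + \varepsilon_t . \]

Each candidate is scored by
\(\Delta\mathrm{AIC} = \mathrm{AIC}_{\mathrm{CP}} -
\mathrm{AIC}_{\mathrm{gradual}}\) (AIC \(= -2\ell + 2\,\mathrm{edf}\));
a CP is accepted when \(\Delta\mathrm{AIC} < -15\), a conservative threshold
that keeps false positives rare. Detection searches every admissible epoch,
splits the series at an accepted CP, and recurses on both halves; a greedy
pruning pass removes CPs that sit too close to each other or to the series
boundaries. Per-patient CP counts are then linked to questionnaire outcomes
(HSCL-11, OQ-30, GAD-7, PHQ-9) by Pearson correlations and first-order
partial correlations adjusting for pre-treatment scores.

Because raw patient stress series of this kind are access-restricted, the
package ships a first-class synthetic generator (`tvcpar.synthetic_data`)
producing piecewise time-varying AR(1) series with the device's bounded
integer scale and both missingness mechanisms (`-1` insufficient data,
`-2` physical activity, plus wholly absent rows).

## Worked example

```python
import warnings
from tvcpar import (RegimeSpec, MissingnessSpec, simulate_stress_series,
                    detect_change_points, final_inertia_model, wear_report)

regimes = [RegimeSpec(0, 18.0, 0.55),       # inertia 0.55
           RegimeSpec(2400, 10.0, 0.80),    # jump to 0.80 on day 6
           RegimeSpec(4700, 30.0, 0.40)]    # jump to 0.40 on day 10
series, truth = simulate_stress_series(
    regimes, MissingnessSpec.realistic(), seed=21)

print("wear:", round(wear_report(series).wear_fraction, 3))
cpset = detect_change_points(series)
models = final_inertia_model(series, cpset)
for cp in cpset.cps:
    print(f"CP at epoch {cp.epoch} ({cp.timestamp:%a %H:%M} UTC), "
          f"delta AIC = {cp.delta_aic:.2f}")
for (a, b), m in zip(cpset.regimes, models):
    print(f"regime [{a:4d},{b:4d}): mean inertia {m.ar_curve.mean():.2f}")
```

prints

```
wear: 0.988
CP at epoch 2475 (Sat 03:45 UTC), delta AIC = -19.44
CP at epoch 4692 (Wed 18:36 UTC), delta AIC = -39.41
regime [   0,2475): mean inertia 0.56
regime [2475,4692): mean inertia 0.79
regime [4692,6720): mean inertia 0.44
```

Both simulated regime shifts (true epochs 2400 and 4700) are recovered
within a few dozen epochs, and the per-regime inertia means track the
generating coefficients 0.55 / 0.80 / 0.40. The series is wear-time
suitable (98.8% of epochs carry a device record; the threshold is a strict
50%).

The same pipeline is available from the shell:

```sh
ema run --seed 1 --out runs/demo          # simulate -> detect -> correlate
ema preprocess --input export.csv         # wear report for a device export
ema detect --input export.csv --out out/  # CP set + inertia curve CSV
```

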