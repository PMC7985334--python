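# Methods

## The model

A patient's stress level \(y_t \in [0,100]\) is observed on a regular
3-minute epoch grid. Within a *regime* — a maximal interval between change
points — dynamics follow a time-varying AR(1),

\[ y_t = f_0(t) + f_1(t)\,y_{t-1} + \varepsilon_t,\qquad
   \varepsilon_t \sim N(0,\sigma^2), \]

with both coefficient paths smooth in time. \(f_1(t)\) is the inertia of
the process. Abrupt change is a shift of both coefficients by constants
\((\delta_0,\delta_1)\) at a change point. The working assumptions are
Gaussian residuals, first-order dynamics only, and instantaneous
stationarity (\(|f_1(t)|<1\)) — the last is deliberately *not* enforced in
estimation, and fitted inertia above 1 is flagged rather than clamped,
because it is informative about residual non-stationarity near change
points.

## Estimation

Each smooth is a cubic B-spline expansion (10 basis functions by default,
knots evenly spaced over the observed epoch range) with a second-order
difference penalty; the varying coefficient enters through the columns
\(B(t)\,y_{t-1}\). Smoothing parameters — one per smooth — are selected by
a Gaussian REML-type criterion with \(\sigma^2\) profiled out
(`smoothing="penalized_ml"`, the default), or by GCV
(`"cross_validation"`). Optimization is a coarse log-\(\lambda\) grid
followed by Nelder–Mead; with a 20-column design every evaluation is a
20×20 Cholesky solve, so fits cost milliseconds even at n ≈ 6,700. The
implementation was cross-checked against an independent penalized-GAM fit
(mgcv, cubic regression splines, REML) on identical data: varying
coefficient curves agree to curve correlation 0.998 and mean difference
~0.001 (frozen in `tests/test_tvcp_ar.py`).

Effective degrees of freedom are the trace of the influence matrix of the
penalized fit; AIC is \(-2\ell + 2\,\mathrm{edf}\) with the Gaussian
maximum-likelihood \(\hat\sigma^2 = \mathrm{RSS}/n\). Which AIC flavour the
original GAM software of reference analyses reports is not standardized
across implementations, so a fixed acceptance threshold may not transfer
exactly between them; the threshold here is interpreted with respect to
this package's AIC definition throughout.

### The CP comparison shares smoothing parameters

Within a search window the CP model reuses the \(\lambda\) selected for
the gradual model on the same pairs, adding the two shift columns
unpenalized. This makes \(\Delta\mathrm{AIC}\) a comparison of nested
penalized fits that isolates the regime shift (and guarantees
\(\mathrm{RSS}_{CP} \le \mathrm{RSS}_{grad}\), hence the nesting bound
\(\Delta\mathrm{AIC} \le 2\,\Delta\mathrm{edf} \le 4\)). Re-selecting
\(\lambda\) per candidate would multiply cost by the number of candidates
while letting smoothness changes masquerade as regime evidence.

### Exhaustive search and recursion

Candidates are all observed response epochs in the window (stride 1 =
exhaustive; a coarser `candidate_stride` is available and validated
against the exhaustive result in tests). A candidate is admissible when
both sides retain at least `min_segment` usable lag pairs and the epoch
keeps `boundary_margin` epochs to the window edges. All candidates are
scored in one vectorized pass via rank-2 Schur-complement updates of the
factorized normal equations (suffix cumulative sums give every candidate's
cross-products in O(np)); the winning candidate is re-evaluated through
the plain per-candidate path so the reported value carries no accumulated
rounding. Detection is recursive binary segmentation: accept the argmin if
its \(\Delta\mathrm{AIC}\) beats the threshold, split, recurse on both
halves (depth cap 12 — with ≥50-pair regimes the cap is never the binding
constraint at n = 6,720). The detector contains no randomness: identical
series and config give identical output.

### Pruning

Collected CPs are pruned greedily by evidence: process in ascending
\(\Delta\mathrm{AIC}\), accept a CP iff it lies ≥ `min_gap` epochs from
every already-accepted CP and ≥ `boundary_margin` epochs from the series
ends; rejected CPs are kept in an exclusion ledger with the reason
(`too_close` / `boundary`). Greedy-by-evidence is a deliberate design
choice: it is order-independent and reproducible, whereas rules tied to
the incidental order of recursion are not reconstructible from output
alone. Final inertia trajectories refit the gradual model independently
per regime, producing a concatenated \(f_1(t)\) with jump discontinuities
at the accepted CPs.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `threshold` | −15 | AIC | conservative; empirically ≤ a few % family-wise false positives at n = 2000 (the null minimum-\(\Delta\mathrm{AIC}\) distribution concentrates above −13) |
| `min_segment` | 50 | lag pairs | ≈ 5 × basis dimension; smallest regime that supports a stable smooth |
| `min_gap` | = `min_segment` | epochs | two CPs closer than this leave too few measurements between them |
| `boundary_margin` | = `min_segment` | epochs | CPs near interval boundaries are poorly identified |
| `candidate_stride` | 1 | epochs | exhaustive search |
| `basis_dim` | 10 | functions/smooth | resolves day-scale drift over two weeks without chasing noise |
| `smoothing` | penalized_ml | — | REML-type selection; GCV available |

## Missing data

An AR lag pair \((y_{t-1}, y_t)\) is usable only when both slots are
observed and grid-adjacent; nothing is imputed, because imputation would
fabricate exactly the autocorrelation being estimated. The three missing
categories (insufficient data −1, physical activity −2, absent row) are
collapsed for modelling. Wear time counts −1/−2 slots as worn — the device
was on but could not, or deliberately did not, compute stress — and
suitability requires a strictly greater than 50% wear fraction. Timestamps
are stored as UTC datetimes; Excel serial conversion (offset 25,569 days
from the Unix epoch) is provided only as an export convenience.

## The synthetic generator

`synthetic_data` emulates the statistical structure the analysis assumes:
a 14-day, 3-minute grid (6,720 epochs); piecewise AR(1) with sinusoidal
within-regime drift (period one day by default) plus step jumps between
regimes — the minimal structure exhibiting both gradual and abrupt change;
observations clipped to [0,100] and rounded to integers (device
granularity); i.i.d. insufficient-data missingness, episodic activity
blocks (Poisson arrivals, geometric lengths), and i.i.d. dropped rows. The
latent state evolves unclipped so that recovery targets stay analytically
clean. Default cohort jump magnitudes (intercept 10–20 stress units, AR
0.15–0.35) were chosen once so that detection is neither trivial nor
hopeless on a two-week grid.

What it does **not** emulate: circadian/ultradian HRV physiology, the
PPG-to-stress computation, posture and exercise artefacts, or any
dependence of missingness on the stress state (missingness is ignorable by
construction). Passing tests therefore demonstrate correctness of the
estimation and detection machinery under the assumed data-generating
class, not robustness to every physiological artefact of real tracker
data.

Cohort outcome linkage: session-15 scores are
\(\text{baseline} + \beta \cdot \#\mathrm{CP} + \text{noise}\) per
instrument, with the slope given in GAD-7 units and rescaled by instrument
range, encoding the direction in which fewer stress change points
accompany more self-reported symptoms.

## Outcome statistics

Listwise complete cases per instrument (pre and session-15 score plus CP
count); the same subset is used for pre-treatment and session-15
correlations — with the bundled seven-patient table this is the six-case
subset, which is the convention under which the shipped correlation table
reproduces its source to two decimals. Sample SDs use the n−1 denominator.
First-order partial correlations use the closed form
\((r_{xy} - r_{xz}r_{yz})/\sqrt{(1-r_{xz}^2)(1-r_{yz}^2)}\), verified
against the residual-on-residual construction to 1e−10. Two-sided
t-distribution p-values (df = n−2, or n−3 for partials) only star entries
at p < 0.05; no multiple-testing correction is layered on. The per-patient
stress-level correlate is the mean of observed stress values over the
analysed window.

## Numerical choices and degenerate inputs

* RSS is floored at 1e−10 per observation so constant series keep a finite
  likelihood; a constant series yields a degenerate-fit warning and no CPs.
* Constant \(y_{t-1}\) triggers a rank-deficiency fallback to an
  intercept-only smooth with a warning.
* Candidate splits with a (near-)singular 2×2 Schur complement are skipped.
* Cholesky failures escalate a tiny ridge before giving up.
* Ties in the candidate argmin resolve to the earliest epoch; pruning ties
  on \(\Delta\mathrm{AIC}\) resolve to the earlier epoch.

## Problem sizes used in validation

Operating characteristics are estimated at the sizes the analyses target:
false positives on 100 stationary series of 2,000 epochs (φ = 0.5);
power/localization on 50 replicates of a strong shift (intercept jump of
three noise SDs, AR 0.3 → 0.8, 3,000 epochs per side); recovery on
constant, ramp and step coefficient paths at n = 2,000–6,000. These sizes
match the two-week grid scale while keeping the whole validation suite
fast.

## Known limitations

* AR(1) only; no higher-order or multivariate dynamics, no Markov
  regime-switching estimation.
* The localization of closely spaced CPs is approximate by construction —
  pruning deliberately refuses to resolve structure finer than `min_gap`.
* The false-positive threshold is calibrated in this package's AIC
  convention; porting the −15 value to other smoothers/AIC variants is not
  guaranteed to preserve the error rate.
* Exact reproduction of any particular patient's CP count from the
  motivating application is out of scope: the raw series are
  access-restricted, so detector validation is property-based on synthetic
  data.
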