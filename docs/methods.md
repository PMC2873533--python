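# Methods

## Model

A real-time PCR amplification trace — one background-subtracted fluorescence
reading per thermal cycle, typically 40 cycles — is described by the
5-parameter Richards function

    F(x) = F_b + F_max · (1 + exp(−(x − c)/b))^(−d)

with background `F_b` (fluorescence units), plateau height above background
`F_max` (> 0), scale `b` (cycles, > 0), location `c` (cycles) and asymmetry
exponent `d` (> 0). The curve is monotone non-decreasing, tends to `F_b` at
early cycles and `F_b + F_max` at the plateau, and reduces to the symmetric
logistic at `d = 1`. Its inflection point sits at `x_f = c + b·ln d`; the
height and tangent slope there have the closed forms

    Y_f = F_max (1 + 1/d)^(−d),
    m   = (F_max/b)(1 + 1/d)^(−(d+1)),

and the normalized asymmetry is `Asym = (F_max − 2Y_f)/F_max =
1 − 2(1 + 1/d)^(−d)` (0 at `d = 1`, → 1 − 2/e ≈ 0.264 as `d → ∞`). `Y_f` is
measured *above background* so that the `d = 1 ⇔ Asym = 0` identity holds
exactly; the closed forms are verified in the test suite against brute-force
numerical differentiation of the model (grid refined to 1e−4 cycles,
agreement to 1e−5 relative).

The key empirical premise is that the fingerprint `y = (F_max, Y_f, m)` is
independent of the input template amount: dilution only translates the curve
along the cycle axis (through `c`). Pooling the standard-curve runs
therefore yields a single trivariate reference with mean `μ` and sample
covariance `Σ` (denominator n−1). Under approximate multivariate normality
the squared Mahalanobis distance `D² = (y−μ)ᵀΣ⁻¹(y−μ)` of a new run is
asymptotically χ² with 3 df; the shape-based outlier call (SOD) is
`D² > χ²₃(0.95) = 7.81` at α = 0.05. The comparator (KOD) standardizes a
run's window-of-linearity efficiency against the standards' efficiencies,
`z = (x_eff − μ_eff)/σ_eff`, and flags `z² > χ²₁(0.95) = 3.84`. Critical
values are always computed from the distribution functions, never
hard-coded; α is configurable.

Ground truth for evaluating either detector is quantification error: with a
fit-point Ct (first upward threshold crossing, linearly interpolated;
threshold 0.4 by default) and the standard curve `Ct = intercept +
slope·log10 N`, the residual `log10(N_ob/N_exp)` over standards is close to
normal with mean ≈ 0; runs outside its 95% interval (mean ± 1.96·SD, bounds
inclusive) are *true* outliers.

## Numerical choices

* **Fitting.** Unweighted least squares by unbounded Levenberg–Marquardt
  (MINPACK via SciPy), started from `F_b` = mean of the first 5 readings,
  `F_max` = max − `F_b`, `c` = first half-maximum crossing, `b = 2`,
  `d = 1`. Estimates outside the plausibility box (`F_max` ≤ 10× the trace
  range, `b ∈ [0.1, 20]`, `d ∈ [0.05, 20]`, `c ∈ [1, 2C]`) or optimizer
  failure mark the fit non-converged — reported, never raised. Exponent
  arguments are clipped at ±700 and the power computed via `log1p`, so the
  model is overflow-safe for any parameter sign the optimizer may visit.
  Flat traces (range < 1e−6) and traces never reaching 10% of a reference
  plateau raise `NoAmplificationError` instead of being force-fitted.
* **Mahalanobis.** Solved through a Cholesky factorization, no explicit
  inverse; covariance condition numbers above 1e12 are rejected. With the
  n−1 covariance the reference distances satisfy `Σ D² = 3(n−1)` exactly,
  which the tests use as an algebraic check. A warning is emitted for
  references below 30 runs, where the asymptotic χ² calibration is rough
  (at n = 72 the true null flag rate is ≈ 6–7%, not 5%, because reference
  estimation error is ignored — visible in the calibration checks' band).
* **Window of linearity.** Contiguous windows of 4–6 cycles whose readings
  lie between 1% and 80% of the run's plateau; the window maximizing R² of
  log10 F vs cycle wins (ties: wider, then earlier start; R² compared at
  12 decimals so float dust cannot flip the tie rule). When the trace
  crosses the quantification threshold, only windows overlapping the
  crossing are eligible (falling back to the unconstrained best), keeping
  the efficiency estimate anchored to the phase the Ct is read in.
  Efficiency is reported as the per-cycle amplification factor `10^slope`
  (2 = perfect doubling).
* **Pipeline policy.** Unfittable test runs are SOD outliers with a
  `D² = +∞` sentinel and reason `"unfittable"`; unfittable standards are
  excluded from the reference (logged). Runs without a window of linearity
  are KOD positives (reason `"undetermined"`). Runs with known input but no
  threshold crossing are labelled true outliers. Rationale in all three
  cases: a run the method cannot evaluate cannot be certified.

## The simulator

`simulate_plate` emulates the standard-curve design the method is meant
for: 6 ten-fold dilutions from 3.14×10⁷ copies, 12 replicates each, 40
cycles. Per run, `(F_max, b, d)` are drawn independently lognormal
(guaranteeing positivity) around (46.41, 2.0, 1.2) with coefficients of
variation (0.13, 0.10, 0.08) — plateau mean and dispersion at the scale of
a well-behaved SYBR-green assay; `c = c_top + (log10 N_top − log10 N)/log10 E`
with `c_top = 14` and nominal efficiency `E = 1.9`; readings are the
Richards curve plus i.i.d. Gaussian noise (SD 0.05, homoscedastic).
Inhibition of strength `s ∈ [0, 1]` applies `F_max ← F_max(1 − 0.6s)`,
`b ← b(1 + s)` and, for the asymmetric kind, `d ← d(1 + 2s)`; the
`plateau_slope_only` kind leaves `d` untouched, mimicking inhibitors that
suppress signal without skewing the curve. The coefficients are qualitative
dose-response knobs chosen to produce monotone plateau/slope suppression
and asymmetry growth; they are config-exposed, not chemistry.
`simulate_inhibition_study` composes one standard plate with test groups
spiked at 3.5×10⁴ copies across a strength ladder, sharing the position
anchor so test Cts are commensurate with the standard curve.

What the generator does *not* emulate: cycle-dependent (heteroscedastic)
noise, correlated `(b, d)` variation (real replicate efficiencies are much
tighter than independent draws imply, so the simulated residual SD,
≈ 0.28 log10 units, is an order larger than a clean instrument run's),
plate/run batch effects, and probe-based chemistries. Passing tests
therefore demonstrate the statistical machinery and the direction of the
inhibition phenomenology, not instrument-level error magnitudes.

## Problem sizes

The default verification workloads are: 100 random parameter sets for the
shape-oracle check, 50 for the Mahalanobis oracle, 2000 null draws (20
references × 100 draws) per detector for calibration, one default 72-run
plate for the concentration-independence check, and 20 simulated inhibition
studies (72 standards + 18 inhibited tests each) for the SOD-vs-KOD
comparison. These sizes give stable Monte-Carlo estimates (binomial SE
≈ 0.005 on the flag rates) while keeping a full run under a minute.

## Known limitations

* The χ²(3) cut-off is asymptotic; no small-sample (Hotelling-type F)
  correction is applied, matching the method as formulated. With n_ref = 72
  the null flag rate sits near 6% rather than 5%.
* No iterative trimming of the reference: standards flagged by SOD itself
  remain in μ/Σ.
* The window-of-linearity search is a self-contained reimplementation of
  the usual conventions (4–6 cycle windows, best R²), not a port of any
  instrument vendor's or published tool's exact baseline iteration;
  per-run efficiencies carry that method variance.
* Robust covariance estimation (e.g. MCD) and alternative multivariate
  classifiers are out of scope by design.
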