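# Methods

## Signal model

A luminol reaction on powdered bone is recorded as an intensity series on
a 15-second grid over 15 minutes. Camera exposure is adjusted per sample
(dimmer, older bones get longer exposures), so raw readings are normalized
to a common reference exposure before comparison. Detector response is
assumed proportional to exposure time:

    corrected = raw · T_ref / T_exp,      T_ref = 30 s by default.

**Ipeak** is the maximum of the corrected sampled values — no smoothing,
no interpolation between bins; ties resolve to the earliest time. The
reference exposure is a configurable convention, not a physical constant:
it rescales all intensities by a common factor and cancels out of every
ratio-based quantity downstream (R², wMAPE, RMSPE, slope ratios).

## Two-phase intensity model

Peak intensity versus PMI (years) is modeled as biphasic:

* **Early phase** (PMI below the breakpoint): exponential decay
  `y = A₁·exp(−(x − x₀)/t₁)`, fitted by unweighted nonlinear least squares
  on the raw intensity scale, initialized from an ordinary regression of
  ln y on x. A₁ and x₀ trade off exactly — only `A₁·e^{x₀/t₁}` is
  identified — so x₀ is fixed at the minimum PMI of the fitted segment by
  default and (A₁, t₁) are estimated. A free-x₀ mode exists for parity
  with three-parameter reports; its per-parameter intervals are flagged
  unreliable because the likelihood is flat along the (A₁, x₀) ridge.
* **Late phase**: ordinary least squares line. A line is deliberately
  minimal: the late segment holds few points and a flexible model there
  would overfit.

A sample lying exactly on the breakpoint is assigned to the late segment.
Samples whose PMI is only approximately known (the ~500-year specimen in
the bundled data) are excluded from all fitting by default: the gap
between 53 and ~500 years contains no data and any fit across it would be
pure extrapolation.

### Uncertainty

Early-phase intensities scatter roughly in proportion to their mean
(multiplicative noise), so the model-based least-squares covariance of the
decay fit undercovers: at σ = 0.1 multiplicative noise and n = 15, the
nominal 95% interval for t₁ covered the truth in only ~79% of 200
replicates. The decay fit therefore reports a heteroscedasticity-robust
sandwich covariance (HC3-type leverage-corrected squared residuals) with
t quantiles at n − p degrees of freedom; measured coverage under the same
conditions is ~93%. The late segment is a tight, near-homoscedastic
plateau, so the linear fit keeps the classical OLS covariance (measured
coverage ~96%).

Mean-response confidence bands use the classical OLS band for the linear
segment and first-order (delta-method) propagation of the parameter
covariance for the decay segment; a seeded residual-resampling bootstrap
(default 2000 resamples) is available as a cross-check. Inverse PMI
prediction propagates the same covariance through
`x = x₀ − t₁·ln(Ipeak/A₁)`.

## Changepoint detection

The breakpoint is located by a slope-ratio grid search on log-transformed
intensities: the natural log of Ipeak linearizes the exponential phase, so
comparing straight-line slopes on each side of a candidate split is
meaningful. For each candidate last-index c of the early segment
(default range 5–19, 1-based on the PMI-sorted data), lines are fitted to
points 1..c and c+1..n and the ratio r_c = slope₁/slope₂ recorded. The
**variation** is the absolute backward difference |r_c − r_{c−1}|; the
optimum is the candidate with the largest variation (smallest index on
ties). When the maximum variation is below a flatness tolerance (default
0.5) the scan reports "no changepoint evidence" rather than an optimum —
on single-phase data all ratios are ≈ 1 and any argmax would be noise.

**Known limitation.** The max-jump criterion localizes the transition
exactly when the late segment is short enough that its one contaminating
point dominates the profile — the regime of the bundled data, where the
early phase holds 17 of 23 points. With a long late segment, or when the
late phase is linear in intensity rather than in log-intensity, the
optimum can land one or more indices early even on noiseless data. The
scan is therefore treated as a screening device whose result should be
inspected (the full ratio profile is exported), not as a consistent
changepoint estimator; no multiple-changepoint or information-criterion
search is attempted because the biphasic hypothesis involves exactly one
transition.

## Influence screening

Cook's distance is computed by the deletion definition
`Dᵢ = Σⱼ(ŷⱼ − ŷⱼ⁽⁻ⁱ⁾)²/(p·s²)` — exactly the classical hat-matrix formula
for the linear model, and a deletion-refit generalization for the decay
model (x₀ stays pinned across deletions so all refits share one model
family). Flagging rules: the 4/n screen (default for the variable early
segment), the classical D > 1 cutoff (default for the late segment, where
4/n at n = 6 would flag a third of the points), and a top-k mode. On the
bundled data the 4/n and top-3 rules agree, excluding the same three
early, high-intensity specimens. Fits with essentially zero residuals
report all distances as zero: deleting a point cannot move an exact fit.

## Cross-validation

Leave-one-out is applied separately to each segment of the final model,
scored by RMSPE (percent). Outlier flags are frozen before validation:
folds re-use the final model's point sets, keeping fold counts stable and
the procedure deterministic. Decay folds start from the full-fit
parameters, which keeps refits robust at segment sizes as small as 13.

## Screening thresholds

In the bundled data every intensity beyond 20 years PMI is below
1000 A.U., and every intensity beyond 30 years below 300 A.U. These two
numbers are exposed as defaults of the presumptive classifier
(`< 300` → long-term phase; `≥ 1000` → early phase; between →
indeterminate; boundary values assigned upward). They are heuristics tied
to this instrument, protocol and skeletal element — every screening result
carries that caveat, and the classifier makes no claim of
calendar-accurate PMI estimation.

## Synthetic data

`generate_biphasic` draws PMIs uniformly on a range (default 7–53 y),
evaluates a piecewise mean (decay below the breakpoint, line above,
optionally continuity-adjusted), and applies multiplicative Gaussian noise
`y = μ(1 + ε)` truncated below at a positive floor. Defaults are
calibrated to the bundled data's fitted regime (A₁ ≈ 8400 A.U.,
t₁ ≈ 5.4 y, late level ≈ 240–270 A.U., σ = 0.2): synthetic tests exercise
the same numeric scales the real analysis sees. `simulate_timecourse`
integrates a bi-exponential rise-then-decay kinetic curve
`I(t) = A(e^{−t/τ_d} − e^{−t/τ_r})` over each trailing exposure window,
adds Gaussian read noise, and samples the 15-s grid; the noiseless curve
peaks at `t* = τ_rτ_d/(τ_d − τ_r)·ln(τ_d/τ_r)`, giving a closed-form
oracle for peak extraction. All generators are pure functions of their
config: same seed, bit-identical output, no global random state.

What the generators do **not** emulate: taphonomic covariates (soil,
temperature, humidity), inter-bone and inter-individual variability,
detector saturation, and the irregular PMI spacing of real casework.
Passing synthetic tests therefore demonstrates correctness of the
statistical machinery under the stated noise model, not field validity of
the screening thresholds.

## Problem sizes in the test suite

Simulation-based properties use sizes at which their targets are sharp but
cheap: 200 replicates for parameter-recovery and interval-coverage checks
(coverage asserted within [88%, 99%] of nominal 95%), 100 seeds for
changepoint-stability checks, n = 15–30 points per synthetic dataset —
matching the scale of the real data. The full suite runs in a few seconds
on one core.
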