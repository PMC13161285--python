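# luminolpmi

Quantitative analysis of luminol chemiluminescence for postmortem-interval
(PMI) screening of human skeletal remains.

When luminol is sprayed on powdered bone it reacts with hemoglobin-derived
iron compounds and emits light; the peak emission intensity (**Ipeak**, in
arbitrary units) decays as hemoglobin degrades after death. This package
implements the statistical pipeline that turns that signal into a
presumptive forensic-vs-archaeological screening tool, for forensic
anthropologists and researchers validating the technique:

* **Peak extraction** — Ipeak from a 15-s-binned emission time course, with
  exposure-time normalization `corrected = raw · T_ref / T_exp`.
* **Changepoint detection** — the intensity–PMI relation is biphasic. On
  log-transformed intensities, straight lines are fitted to each side of
  every candidate split; the ratio of their slopes jumps at the phase
  transition, and the optimum is the candidate with the largest consecutive
  change in that ratio. On the bundled data this places the transition
  between 27 and 34 years (breakpoint ≈ 30.5 y).
* **Segmented regression** — below the breakpoint an exponential decay
  `y = A₁·exp(−(x − x₀)/t₁)`; above it a line `y = a + b·x`, each screened
  separately for influential points by Cook's distance
  `Dᵢ = Σⱼ(ŷⱼ − ŷⱼ⁽⁻ⁱ⁾)² / (p·s²)`.
* **Validation** — per-segment leave-one-out cross-validation scored by
  RMSPE = 100·√(mean(((y − ŷ)/y)²)); fit quality by R² and
  wMAPE = Σ|y − ŷ| / Σ|y|.
* **Screening** — intensities below 300 A.U. are consistent with the
  long-term phase (PMI ≳ 30 y); at or above 1000 A.U. with the early phase
  (PMI ≲ 20 y). Within the fitted early-phase range the decay inverts to a
  PMI estimate `x = x₀ − t₁·ln(Ipeak/A₁)` with a delta-method interval.
* **Synthetic data** — seeded generators for biphasic Ipeak–PMI datasets
  and rise-then-decay kinetic time courses, so every stage is testable.

The bundled dataset transcribes the published measurements of 24 human
clavicles with PMIs from 7 to ~500 years; the ~500-year specimen is flagged
approximate and excluded from fitting by default.

## Worked example

```sh
python examples/fit_bundled_dataset.py
```

prints (abridged):

```
changepoint scan (candidates 5-19): early phase ends at point 17,
transition 27 -> 34 years, breakpoint 30.5 years

Segment 1 (PMI < 30.5 y, exponential decay)   A1 (A.U.)    5160.913
                                              t1 (years)      5.355  (1.89, 8.82)
                                              x0 (years, fixed)  11.000
Segment 2 (PMI > 30.5 y, linear)              intercept (A.U.)  371.196  (280.10, 462.29)
                                              slope (A.U./year)  -3.109  (-5.25, -0.97)

Segment 1: R^2 = 0.8645, wMAPE = 0.2288, n = 14, excluded = [1, 2, 5]
Segment 2: R^2 = 0.8029, wMAPE = 0.0269, n = 6, excluded = []

LOOCV RMSPE: early segment 37.31% (14 folds), late segment 6.17% (6 folds)
```

Read: intensity falls with a ~5.4-year time constant through the first
three decades postmortem, then settles on a shallow plateau
(−3.1 A.U./year). Three early samples were excluded as influential
(Cook's distance). The late phase predicts new intensities to ~6%, the
early phase only to ~37% — early-PMI intensities are dominated by
taphonomic variability, so PMI estimates there are screening-grade only.

Other examples: `screen_unknown_sample.py` (phase calls and inverse PMI
estimates), `extract_peak_from_timecourse.py` (Ipeak from a simulated
acquisition), `simulate_and_recover.py` (parameter recovery on synthetic
data). A thin CLI wraps the same stages:

```sh
luminol-pmi pipeline --input fixture --breakpoint auto --out results/
luminol-pmi classify 218.68
```

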