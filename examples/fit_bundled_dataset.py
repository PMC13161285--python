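"""Full analysis of the bundled clavicle dataset.

Runs the changepoint scan, fits the two-phase model (exponential decay
below the breakpoint, line above), and cross-validates each segment.
Printed numbers: the breakpoint in years, per-segment parameters with 95%
confidence intervals, R^2 and wMAPE on the retained points, and the
leave-one-out RMSPE — the percent-scale prediction error a practitioner
should expect for a new bone of that phase.
"""

import luminolpmi as lp

ds = lp.load_fixture()
print(f"loaded {len(ds)} samples; approximate-PMI ids excluded by default: "
      f"{sorted(ds.approximate_ids)}\n")

scan = lp.scan_changepoint(ds)
a, b = scan.optimal_transition_pmi
print(f"changepoint scan (candidates 5-19): early phase ends at point "
      f"{scan.optimal_last_index}, transition {a:g} -> {b:g} years, "
      f"breakpoint {lp.breakpoint_value(scan):g} years\n")

model = lp.fit_segmented(ds, breakpoint_years=lp.breakpoint_value(scan))
print(lp.report_text(model))

res1, res2 = lp.loocv_model(model)
print(f"\nLOOCV RMSPE: early segment {res1.rmspe_percent:.2f}% "
      f"({res1.n_folds} folds), late segment {res2.rmspe_percent:.2f}% "
      f"({res2.n_folds} folds)")
print("The late phase is an order of magnitude more predictable: beyond the "
      "breakpoint, intensities are low and nearly constant.")
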