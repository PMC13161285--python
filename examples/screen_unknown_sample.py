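"""Presumptive triage of unknown bone samples from their peak intensity.

A corrected Ipeak below 300 A.U. is consistent with the long-term phase
(PMI beyond ~30 years, archaeological-leaning); at or above 1000 A.U. it
is consistent with the early phase (PMI under ~20 years, forensic-
leaning).  For intensities inside the fitted early-phase range the decay
curve is inverted to a PMI point estimate with a delta-method interval.
All calls are presumptive: thresholds are instrument-specific heuristics.
"""

import luminolpmi as lp

model = lp.fit_segmented(lp.load_fixture(), breakpoint_years=30.5)

for ipeak in (4200.0, 650.0, 218.68):
    res = lp.predict_pmi(model, ipeak)
    line = f"Ipeak {ipeak:8.2f} A.U. -> {res.phase_call:16s}"
    if res.pmi_point_estimate is not None:
        lo, hi = res.pmi_interval
        line += f" PMI ~ {res.pmi_point_estimate:5.1f} y (95% CI {lo:.1f}-{hi:.1f})"
    else:
        line += " (flat late phase: no PMI point estimate possible)"
    print(line)

print("\nCaveat:", res.caveat)
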