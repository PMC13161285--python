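"""Parameter recovery on synthetic biphasic data.

Generates an Ipeak-vs-PMI dataset from a known two-phase truth (decay
time constant t1 = 5.4 y, late slope -3.1 A.U./y) with 10% multiplicative
noise, fits the segmented model at the true breakpoint, and prints the
estimates next to the truth.  With moderate noise both should agree to
within the reported confidence intervals.
"""

import luminolpmi as lp
from luminolpmi.synthetic import BiphasicConfig, generate_biphasic

cfg = BiphasicConfig(n=30, noise_sigma=0.1, seed=2024)
ds = generate_biphasic(cfg)
model = lp.fit_segmented(ds, breakpoint_years=cfg.breakpoint_years,
                         seg1_rule=lp.TopK(0), seg2_rule=lp.TopK(0))

t1_lo, t1_hi = model.seg1.ci95[1]
sl_lo, sl_hi = model.seg2.ci95[1]
print(f"true t1   = {cfg.t1:6.2f} y      estimated {model.seg1.t1:6.2f} "
      f"(95% CI {t1_lo:.2f}-{t1_hi:.2f})")
print(f"true slope= {cfg.slope:6.2f} A.U./y estimated {model.seg2.slope:6.2f} "
      f"(95% CI {sl_lo:.2f}-{sl_hi:.2f})")
print(f"segment R^2: early {model.seg1.r2:.3f}, late {model.seg2.r2:.3f}")
print("Each interval should cover its generating value at roughly the "
      "nominal 95% rate across repeated seeds.")
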