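"""Evaluate the hit-statistics survival model and its analytic limits.

A two-hit model typical of low-LET x-rays: each energy-deposition event
("hit") deposits z_F = 1 Gy in the sensitive volume on average; cells
always survive one hit (s1 = 1), survive two hits 35% of the time, and
never survive three or more.
"""

import numpy as np

from hitsurv import (
    SurvivalModel,
    asymptotic_slope,
    lq_alpha,
    lq_beta,
    survival,
    zf_upper_bound,
)

model = SurvivalModel(z_f=1.0, s=(1.0, 0.35))

print("dose (Gy)   surviving fraction")
for dose in [0, 1, 2, 5, 10, 14]:
    print(f"{dose:9.1f}   {survival(model, float(dose)):.4g}")

alpha, beta = lq_alpha(model), lq_beta(model)
print(f"\nLQ limit at low dose: alpha = {alpha:.3f} /Gy, beta = {beta:.3f} /Gy^2")
print(f"high-dose slope of -ln S: {asymptotic_slope(model):.3f} /Gy (= 1/z_F)")
print(f"upper bound from (alpha, beta): z_F,max = {zf_upper_bound(alpha, beta):.3f} Gy")

# The curve has a shoulder (alpha = 0 here: single hits are always
# survivable) and turns into a straight line of slope 1/z_F once most
# surviving cells carry the maximum repairable damage.
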