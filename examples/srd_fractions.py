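"""How sublethal damage partitions the surviving population.

Among cells that survive a dose D, the fraction that received exactly k
hits is f_k = s_k h_k / S.  With increasing dose the undamaged class f0
shrinks and the maximally damaged (most radiosensitive) class dominates —
the mechanism behind the constant terminal slope of survival curves.
"""

import numpy as np

from hitsurv import SurvivalModel, surviving_fractions

model = SurvivalModel(z_f=1.0, s=(1.0, 0.35))

print("dose (Gy)    f0      f1      f2")
for dose in [0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 10.0]:
    f = surviving_fractions(model, dose).fractions
    print(f"{dose:8.1f}  {f[0]:.4f}  {f[1]:.4f}  {f[2]:.4f}")

# At 1 Gy about 46% of survivors are undamaged, 46% carry one hit and 8%
# carry two; past ~4 Gy the two-hit class (one more hit is lethal) is the
# largest, so each further dose increment kills at the single-hit rate
# 1/z_F — the survival curve has become a straight line.
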