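"""Sensitive-volume radius from the spherical specific-energy relation.

Given z_F (or its upper bound) and the frequency-mean lineal energy y_F,
the SV radius solves z_F = 0.1602 * y_F / (pi * rho * R^2).  Using the
upper bound z_F,max yields the lower-bound radius R_min.
"""

import math

import pandas as pd

from hitsurv import (
    LetApproximation,
    MicrodosimetryTable,
    solve_radius,
    zf_from_radius,
)

# 100 MeV protons: y_F ~ LET = 0.74 keV/um, z_F,max = 2.59 Gy from the
# proton trend -0.31*ln(LET) + 2.5
z_f = -0.31 * math.log(0.74) + 2.5
r_min = solve_radius(LetApproximation(), 0.74, z_f)
print(f"100 MeV protons: z_F,max = {z_f:.2f} Gy -> R_min = {r_min:.3f} um")

# with a tabulated y_F(R) (synthetic plateau-shaped table): y_F varies
# only weakly with R, so the solution barely moves
table = MicrodosimetryTable(
    data=pd.DataFrame(
        {
            "particle": ["proton"] * 3,
            "let_kev_um": [0.74] * 3,
            "radius_um": [0.05, 0.25, 0.5],
            "yf_kev_um": [0.79, 0.76, 0.74],
        }
    ),
    provenance="synthetic plateau table",
)
prov = table.provider("proton")
r_tab = solve_radius(prov, 0.74, z_f)
print(f"with the tabulated y_F(R):              R_min = {r_tab:.3f} um")
print(f"round trip z_F at that radius: {zf_from_radius(prov, 0.74, r_tab):.2f} Gy")
# R_min ~ 0.1 um points at a DNA-scale target; R_min grows with LET
# because the sensitive volume also reflects the spatial extent of damage.
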