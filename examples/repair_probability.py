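"""Can a cell repair between consecutive hits during a fraction?

Hits arrive as a Poisson process at rate a = dose_rate / z_F; repair is
exponential with rate ln2 / half-time.  P_R is the probability that
repair of one hit's damage completes before the next hit, within the
fraction delivery window.
"""

from hitsurv import (
    RepairScenario,
    SimulationConfig,
    fraction_hit_count,
    repair_completion_prob,
    simulate_repair_window,
)

# 2 Gy fraction of 100 MeV protons at 0.05 Gy/s; 1 h repair half-time;
# z_F = 2.59 Gy from the proton z_F,max trend at LET = 0.74 keV/um
scenario = RepairScenario(
    dose_rate=0.05, fraction_dose=2.0, z_f=2.5933, repair_half_time=3600.0
)

print(f"fraction delivery time: {scenario.fraction_time:.0f} s")
print(f"mean hits per fraction: {fraction_hit_count(scenario):.3f}")
p = repair_completion_prob(scenario)
print(f"P_R (closed form):      {p:.4f}")

mc = simulate_repair_window(scenario, SimulationConfig(n_samples=10 ** 6, seed=1))
print(f"P_R (Monte Carlo):      {mc.value:.4f} +/- {mc.se:.4f}")

# P_R ~ 0.002: repair is ~100x slower than the delivery, so sublethal
# damage accumulates essentially un-repaired within a fraction.
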