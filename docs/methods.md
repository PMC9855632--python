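# Methods

## Model

Survival is a mixture over the Poisson-distributed number of
energy-deposition events ("hits") on a sensitive volume (SV):

    S(D) = e^{-N} Σ_{k≥0} s_k N^k / k!,   N = D / z_F,   s_0 = 1.

A *hit* is all energy deposited in the SV by one particle track (primary
plus secondaries) — counting per track is what justifies the Poisson law.
z_F, the frequency-mean specific energy (Gy), is the average dose to the
SV per event; s_k is the probability of surviving k hits, absorbing
repair, LET and dose-rate biology into a small set of probabilities.

Two parameterizations:

* **truncated** — s_k = 0 for k > K: survivable sublethal damage is
  capped. The series is a degree-K polynomial times e^{-N}; ln S is LQ at
  low dose (α = (1−s_1)/z_F, β = (s_1²−s_2)/2z_F²) and exactly linear at
  high dose with slope 1/z_F. This is the working model throughout.
* **independent_repair** — each hit's damage is repaired independently, so
  s_i = s_1^i and the series sums to exp(−N(1−s_1)): a straight line of
  slope (1−s_1)/z_F, the regime reported for ultrasoft x-rays.

Assumptions worth stating: hits are exchangeable (no track structure, no
spatial correlation between hits); s_k do not depend on dose or dose rate;
s_2 ≤ s_1² (surviving a second hit can be no easier than the first), which
makes β ≥ 0. The last is enforced only as a warning because fitted
parameters can cross it within noise. Whether s_k must be monotone
non-increasing in k is not derivable from the model; it is available as an
opt-in constraint (`require_monotone`), default off.

## Parameters

| parameter | units | meaning | typical |
|---|---|---|---|
| z_F | Gy | specific energy per event; sets N = D/z_F and the terminal slope 1/z_F | ~1 Gy photons, ~2.6 Gy low-LET protons, ≤0.5 Gy heavy ions |
| s_1, s_2, … | — | survival probability after k hits | s_1 ≈ 0.8–1 (photons) down to ≈0.5 (protons) at z_F = 1 Gy |
| K | — | highest survivable hit count | 2 for the reference x-ray data |
| ρ | g/cm³ | SV density in the radius relation | 1.0 (default, overridable) |
| C | — | unit constant in z_F = C·y_F/(πρR²) | 0.1602 fixed |

C converts (keV/μm, μm, g/cm³) to Gy: 1 keV = 1.602×10⁻¹⁶ J and 1 μm³ of
unit-density material weighs 10⁻¹⁵ kg.

## Estimating z_F

**Bounds (method 1).** Each (α, β) record yields
z_F,max = 1/(α + √(2β)); α = β = 0 gives an unbounded record, returned as
`inf` and dropped from regressions. Trends of z_F,max versus ln LET are
fitted by iteratively reweighted least squares with a Huber loss
(tuning constant 1.345, 95% Gaussian efficiency, via statsmodels RLM) —
literature compilations carry gross outliers. 95% bands are nonparametric
bootstrap over records (1000 resamples, fixed seed), clipped to enclose
the point estimate. Records are unweighted: published compilations rarely
carry usable per-record uncertainties. Prediction at a new LET propagates
the coefficient covariance; queries outside the fitted LET range are
flagged as extrapolations rather than refused — the proton trend must be
evaluated at 0.74 keV/μm, slightly below its fitted range, to reproduce
the 100 MeV proton numbers.

**Terminal slope (method 2).** At high dose −d ln S/dD → 1/z_F. The
linear segment is found by anchoring a window at the highest dose and
growing it leftward while (a) a Wald–Wolfowitz runs test on the residual
signs of the running linear fit stays above p = 0.05 and (b) the slope
moves by less than one standard error per added point; minimum three
points, all thresholds configurable. An essentially perfect fit
(residuals < 10⁻¹⁰ of the data scale) passes outright, since both
criteria degenerate on exactly linear data. z_F = −1/slope from weighted
least squares over the segment, with se(z_F) = se(slope)/slope².

The slope estimator is biased high at moderate doses: the local slope is
1/z_F · (1 − p'(N)/p(N)) with p the survival polynomial, and p'/p decays
only like K/N. For the reference model (z_F = 1 Gy, K = 2) the window
10–16 Gy gives 1.15 Gy, 30–36 Gy gives 1.06 Gy, 80–86 Gy gives 1.02 Gy.
Tests assert this convergence rather than pretending the bias away; users
should fit the deepest survival levels available.

**Full fits.** Bounded nonlinear least squares on ln S (survival spans
several decades, and assay noise is roughly multiplicative), weighted by
per-point uncertainties when present, parameters z_F ∈ [10⁻³, 10³] Gy and
s_k ∈ [0, 1]. Multi-start from the deterministic grid
z_F ∈ {0.25, 0.5, 1, 2, 4} Gy × s_k ∈ {0.1, 0.5, 0.9}^K, first best wins
ties. Standard errors from the Gauss–Newton curvature scaled by the
residual variance. On noiseless data the optimum sits on a degenerate
ridge where the optimizer can exhaust its evaluation budget at an
essentially perfect fit; the best point is accepted when the first-order
optimality is below 10⁻⁸ or the cost below 10⁻¹⁶, otherwise a diagnostic
error carries the best attempt.

**Order selection.** Fit K = 0…K_max; choose the smallest K whose next
parameter is noise: |ŝ_{K+1}| ≤ max(se, 10⁻⁶). The floor handles
noiseless data, where the residual variance — and with it the standard
error — collapses to zero and the rule would be undecidable.

## SV radius

z_F = C·y_F(E, R)/(πρR²) has a unique root in R because y_F varies only
weakly with R (it plateaus above a few tenths of a μm). The solver
verifies monotone decrease of the right-hand side on a 64-point log grid
over [10⁻³, 50] μm before bisecting (Brent, relative tolerance 10⁻⁶);
non-monotone providers and bracket-sign failures raise distinct errors.
y_F comes from a provider: tabulated values interpolated log-linearly
along energy/LET and linearly along radius, with plateau (constant)
extension beyond the tabulated radius range and a strict out-of-range
error along the key axis; or the approximation y_F ≈ LET, appropriate
when the track traverses the SV. Tabulated photon y_F sources are
external measurements, so photon radii computed here with surrogate
tables are approximate by construction; the proton result is insensitive
to this because y_F ≈ LET holds well at 100 MeV.

## Repair within a fraction

Hits arrive at rate a = Ḋ/z_F; inter-hit intervals are exponential.
With exponential repair (rate μ = ln2/half-time — single-component
kinetics only),

    P_R = μ/(μ+a) − e^{−a t_f} (1 − a e^{−μ t_f}/(a+μ)),

the total-probability integral of completing repair before the next hit
within the fraction time t_f. The closed form is cross-checked against
adaptive quadrature (10⁻¹⁰) and a sampling oracle. The expression, as
defined, does not condition on a next hit actually occurring inside the
fraction; that is the quantity of interest here (no hit, no accumulation).

## Synthetic data

The generators emulate the two kinds of published inputs at their real
scale:

* survival curves: closed-form S times multiplicative lognormal noise
  exp(σε) — clonogenic assays scatter with roughly constant relative
  error, and the noise keeps S > 0. Default study conditions follow the
  reference x-ray analysis: z_F = 1 Gy, s = (1.0, 0.35), doses 1–14 Gy in
  1 Gy steps, σ = 0.05. Observations are clipped at S = 1.
* (α, β, LET) compilations: LET log-uniform over the compilation range
  (0.42–73.2 keV/μm, n = 91 for the proton-like set), z_F,max on the
  given trend plus Gaussian scatter (truncated at 0.05 Gy), and each
  record's (α, β) split drawn so the record sits exactly on its z_F,max:
  α = t/z, β = (1−t)²/2z² with t ~ U(0,1). Gross outliers at the chosen
  rate get one-sided upward shifts of 1.5–3 Gy.

What the generators do **not** emulate: inter-laboratory heterogeneity,
correlated (α, β) errors within a study, dose-dependent assay noise,
LET-dependent s_k, and real microdosimetric spectra. Passing recovery
tests therefore demonstrates the estimators' correctness and robustness
under the stated noise model, not fidelity of any particular published
dataset.

Reproducibility: every simulator derives its generator as
`default_rng([master_seed, salt])` with a fixed per-operation salt, so
operations draw from independent streams and all outputs are
bit-reproducible under a fixed seed.

## Numerical choices

* ln S is evaluated exactly as polynomial × e^{-N} for N ≤ 30 and by
  log-sum-exp over ln s_i + i ln N − ln i! above that; naive evaluation
  under/overflows at radiotherapy-relevant N. Agreement with exact
  rational arithmetic is tested to 10⁻¹⁰ relative for N ≤ 50.
* Damage fractions f_k are computed as a normalized log-domain weight
  vector, so Σf_k = 1 exactly at any dose.
* Derivative cross-checks use central differences with step 10⁻⁴·z_F,
  Richardson-extrapolated to D = 0 (the stencil cannot straddle zero
  dose).
* Infeasible (s_1, s_2) from the (α, β) inversion are reported with a
  flag, never clamped: infeasibility is the signal that the assumed z_F
  exceeds its bound.
* Test problem sizes: Monte-Carlo oracles run at 10⁶ samples (binomial
  se ≈ 5×10⁻⁴ at S = 0.5), oracle sweeps over 20 randomized scenarios,
  recovery studies over 50 seeds; these keep the full suite under a
  minute of simulation time while leaving comparisons at ≥3σ resolution.

## Known limitations

* s_k carry no explicit dose-rate or LET dependence; the repair module
  quantifies when that matters (P_R ≪ 1 for clinical delivery).
* No cell-cycle, oxygen or bystander effects; aerobic data only.
* The damage-fraction profile is defined for the truncated model only
  (finite support); independent-repair mode raises.
* Multi-exponential repair kinetics are out of scope.
* The terminal-slope estimator's O(K/N) bias means method 2 needs data
  reaching deep survival levels; the segment detector cannot manufacture
  asymptotic behaviour that the data do not contain.
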