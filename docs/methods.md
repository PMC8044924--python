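# Methods

## Scope and data model

`nrfr` analyses endpoint grazing experiments: each experimental unit (a
"well") contributes initial and final predator counts (N₀, N_t,
cells/ml), initial and final prey counts (P₀, P_t), a predator-free
control at the same nominal food level (C₀, C_t), the incubation length
t (days), and the prey's per-cell carbon content m (pg C/cell). Prey
quantities are carried internally in ng C/ml; fitted response-curve
parameters and all figure axes use mg C/liter (1 mg C/liter = 1000
ng C/ml exactly, so the conversion is lossless and round-trips to
machine precision).

## Endpoint rate estimators

Assuming exponential change between the two sampling points:

* μ = ln(N_t/N₀)/t — predator specific growth rate; negative values are
  legitimate observations (mortality exceeding division) and are kept.
* P̄ = (P_t − P₀)/ln(P_t/P₀) — the time-averaged (geometric-mean) prey
  level of an exponentially changing batch, continuous at P_t = P₀
  (where it returns P₀; the switch uses a relative tolerance of 1e-9).
* g = [ln(C_t/C₀) − ln(P_t/P₀)]/t — grazing rate: control prey growth
  minus apparent prey growth in the grazed treatment. Negative g
  (treatment prey outgrowing the control) is retained and flagged.
* I = P̄·g/R_m — per-predator ingestion, with R_m the mean predator
  abundance. R_m uses the same time-average form (N_t − N₀)/ln(N_t/N₀)
  by default; the arithmetic mean is available as an option since the
  choice is a convention, not a derivation. Negative I is clipped to 0
  by default (with a flag) because FR models are defined for I ≥ 0;
  clipping can be disabled.

Wells whose predators die out completely (N_t = 0) are marked `extinct`:
μ is undefined there (not −∞), the record is excluded from response fits,
and the exclusion is counted in the QC flags of the rates table.

## Response-curve fitting

**Numerical response.** μ(P) = μ_max(P − P′)/(k₂ + P − P′), fitted by
bounded nonlinear least squares (scipy's trust-region reflective
Levenberg–Marquardt variant) with bounds μ_max ∈ (0, 20], k₂ ∈ (0, 100]
(both in their natural units), P′ ∈ [0, max P]. The optimizer is started
from five deterministic heuristic points — μ_max⁰ = max observed μ;
P′⁰ = the largest P with μ ≤ 0 (else min P/2); k₂⁰ ∈ {¼, ½, 1} × the
P-range; plus a P′ = 0 start and an inflated-μ_max start — and the best
converged start wins on residual sum of squares. A fit is flagged (not
silently accepted) when an estimate sits on a bound, when the
information matrix is singular, or when k₂ runs to either degenerate
limit (k₂ → 0 gives a step, k₂ → ∞ a rescaled line; both mean the data
carry no hyperbolic signal).

Standard errors come from the Wald covariance (SVD-based inverse of
JᵀJ, scaled by the residual variance with df = n − 3); p-values are
two-sided t-tests of estimate/SE on n − 3 df. Confidence *intervals*
for the strictly positive parameters μ_max and k₂ are Wald intervals on
the log scale mapped back — the standard construction for
positivity-constrained scale parameters, whose sampling distributions
are visibly right-skewed at realistic design sizes (24 wells). P′ may
genuinely be zero, so its interval stays on the natural scale. The
reported SEs themselves are natural-scale throughout. α = μ_max/k₂ is
computed from the unrounded estimates with a delta-method SE.
Confidence bands for the fitted curve use the delta method by default;
a seeded parametric bootstrap (default 1000 draws from the asymptotic
normal) is available as a cross-check.

**Functional response.** Both candidates are always fitted: Holling II
I(P) = I_max·P/(k + P) by bounded least squares (multi-start on k), and
the zero-intercept line I(P) = slope·P in closed form. Selection is by
AICc (Gaussian likelihood, error variance counted as a parameter).
Independently of AICc, the Holling fit is declared *divergent* when its
parameters run to the bounds or a standard error exceeds its estimate —
the signature of data with no saturation inside the observed food range,
in which case the linear model is reported regardless of AICc. Both
candidate fits are always retained in the results object.

**GGE.** Gross growth efficiency GGE = μ·M/I (M the predator's cellular
carbon, ng C/cell) is evaluated by default only at the moderate
reference level 0.5 mg C/liter, because per-cell prey carbon is
typically measured near that level; values outside [0, 1] draw a
warning rather than an error (they occur legitimately through
measurement noise), and GGE is undefined for I ≤ 0.

Reference food levels default to {0.5, 2.0} mg C/liter — conventional
"moderate" (oligo-mesotrophic peak) and "high" (eutrophic) prey
biomasses — and are configurable.

## Allometry and units

Cell volume comes from length/width under a geometric idealization:
prolate ellipsoid (π/6)LW², flattened ellipsoid (π/6)LW·(rW) with depth
ratio r (default 2/3, configurable; used when no depth measurement
exists), rod π(W/2)²L, sphere (π/6)L³. Volume converts to per-cell
carbon with class-specific power laws C = aV^b, shipped as three named
built-ins: ciliates (0.216·V^0.939, pg C), small algae (0.261·V^0.860,
pg C), bacterioplankton (133.754·V^0.438, fg C). The output unit is
fixed per law and never inferred; helpers convert to ng and to biomass
concentrations. Additional laws load from YAML.

## Bacterial-contamination sensitivity analysis

Non-axenic cultures carry a bacterial background that co-varies with the
algal food level. Three operations bound its effect: (1) an OLS
calibration line of bacterial versus algal biomass from a small number
of DAPI-count calibration points (negative predictions are clipped at 0
with a warning — few calibration points constrain the intercept poorly);
(2) a refit of both response curves with each well's prey biomass
augmented by the predicted bacterial biomass, reporting parameter deltas
— note the threshold model is translation-covariant in P, so a constant
bacterial offset c moves P̂′ by exactly +c and leaves μ̂_max, k̂₂
unchanged, a property the tests verify exactly; (3) a worst-case
clearance extrapolation: uptake = clearance × bacterial density ×
per-cell carbon, reported per hour and per day, with the implied
additive shift of I_max. Bacterial growth during the incubation enters
as a doublings parameter (0–3) through the same geometric-mean time
average used for prey; it defaults to 0 for the regression path and is
only meant for worst-case arithmetic. No two-resource functional
response is modelled — bacteria are treated strictly as an additive
biomass perturbation.

## Synthetic experiments

The generator reproduces the microcosm design the estimators were built
for: 24 wells, initial prey 10³–10⁵ cells/ml on a geometric progression
(per-step factor uniform in [1.1, 1.5], rescaled in log space so the
series ends exactly at the range maximum; a fixed factor is also
supported), predator inoculum 20 cells/ml, 48-h incubation, one
predator-free control per food level.

Within a well the latent dynamics are the coupled batch ODE

    dA/dt = μ_prey·A − (I(P)/m)·R,   dR/dt = μ(P)·R,

integrated with LSODA at rtol 1e-8 (A prey cells/ml, R predators/ml,
P = A·m in carbon units); the control is the exact exponential
C(t) = C₀e^{μ_prey t}. Counting noise is Poisson on *counted cells*:
predators are counted in the full 1-ml subsample (≈10–50 cells), prey in
a subsample sized to a target of ~400 counted cells (the middle of the
typical 200–600), bounded between 1 µl and 1 ml. Initial-count draws are
redrawn if zero (an empty inoculum would be caught before a real
experiment starts); final counts may be zero (extinction). Prey growth
rates in the controls are free parameters — they are not published for
the food alga — with defaults 0.10/0.20/0.30/0.35/0.40 d⁻¹ at
5/10/15/18/20 °C, plausible batch rates for a cryptophyte, chosen once
and configurable.

Because the endpoint estimators assume piecewise-exponential change
while the simulator integrates the true coupled system, a small
systematic bias exists by construction (≈0.1 % on μ_max, a few percent
on I_max at the default conditions); `parameter_recovery_suite`
quantifies it rather than hiding it. The recovery suite spawns
per-replicate seeds from one root `SeedSequence` (all below 2³¹), refits
each simulated plate, and reports bias, RMSE and Wald-interval coverage
per NR parameter. At the default design with the 15 °C ground truth the
measured 95 % interval coverages are ≈0.95 (μ_max), 0.92 (P′), 0.93
(k₂) over 1000 replicates.

What the simulator does *not* emulate: within-well acclimation
adjustments, bottle/wall effects, predator interference, prey
selectivity, non-Poisson counting error (clumping), and bacteria–algae
two-resource dynamics. Passing recovery tests therefore demonstrate the
estimators' correctness under the design's sampling noise, not
robustness to those unmodelled features of real data.

## Problem sizes and numerical choices

The test suite runs simulation-based checks at 150–500 replicates of the
24-well design — enough to estimate coverages and selection frequencies
to ±0.01–0.03 — and the whole suite completes in well under a minute of
CPU. Ties and degenerate inputs are handled explicitly: equal endpoint
ratios return the continuous limit of the geometric mean; flat growth
responses are flagged non-identifiable instead of returning an arbitrary
k₂; CSV round-trips use round-trip float parsing so simulated plates
survive serialization bit-exactly.

## Known limitations

* Wald inference is asymptotic; at 24 points the intervals for k₂ are
  approximate even on the log scale (coverage ≈0.93, not 0.95).
* Unweighted least squares ignores the heteroscedasticity of
  count-derived growth rates (noise is largest at low food); this
  matches standard practice for these curves but slightly inflates the
  low-food influence of noisy wells.
* The endpoint grazing estimator attributes any treatment/control
  difference in prey growth to grazing; systematic treatment effects on
  the prey (e.g. nutrient regeneration by the predator) would bias g.
* Only endpoint (two-timepoint) designs are supported; no time-series
  fitting, no type-III responses, no multi-prey models, and no
  across-temperature (Arrhenius/Q₁₀) modelling — temperatures are fitted
  independently.
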