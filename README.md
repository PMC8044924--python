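# nrfr — numerical & functional response analysis for protist grazing experiments

Planktonic protists (ciliates, heterotrophic flagellates) are bottom-up
controlled by their food supply, and the standard way to quantify that
control is a pair of response curves measured in batch microcosms:

* the **numerical response (NR)** — predator per-capita growth rate μ as a
  function of prey biomass *P*, fitted here with a Michaelis–Menten-type
  hyperbola shifted to cross zero at a positive prey threshold *P*′:

  μ(P) = μ_max (P − P′) / (k₂ + P − P′)

  with μ_max the asymptotic maximum growth rate (d⁻¹), *P*′ the threshold
  prey concentration where growth balances mortality (mg C/liter), k₂ a
  shape constant (mg C/liter, *not* the Michaelis half-saturation
  constant), and α = μ_max/k₂ the low-food affinity (initial slope);

* the **functional response (FR)** — per-predator ingestion rate *I*
  versus prey biomass, either Holling type II, I(P) = I_max·P/(k + P),
  or — when the data never saturate within the observed food range — a
  zero-intercept line I(P) = slope·P, chosen by AICc with an independent
  divergence check.

`nrfr` implements the complete quantitative pipeline around those fits
for endpoint (t₀/t₂) experiments: Frost/Heinbokel endpoint rate
estimators (growth, geometric-mean prey, grazing, ingestion),
biovolume→carbon power-law allometry with strict unit handling, gross
growth efficiency (GGE = μ·M/I), a bacterial-contamination sensitivity
analysis, and a ground-truth microcosm simulator (coupled prey/predator
ODE + Poisson counting noise) for validating the estimators by parameter
recovery. It is aimed at aquatic microbial ecologists running plate- or
bottle-based grazing experiments.

## Worked example

Models follow the Model → `fit()` → Results idiom. Simulate one 24-well
plate at 15 °C with known truth (μ_max = 0.45 d⁻¹, P′ = 0.10,
k₂ = 0.18 mg C/liter; Holling-II ingestion I_max = 28.54 ng C cell⁻¹ d⁻¹,
k = 4.09 mg C/liter), estimate the per-well rates, and refit:

```python
from nrfr import (ExperimentDesign, FunctionalResponse, GeneratingModel,
                  NumericalResponse, gross_growth_efficiency, rates_table,
                  simulate_experiment)

gm = GeneratingModel(nr=(0.45, 0.10, 0.18), fr_holling=(28.54, 4.09),
                     species="V. natans")
exp = simulate_experiment(gm, ExperimentDesign(temperature_c=15), seed=42)
rates = rates_table(exp.wells)          # per-well mu, P_mean, g, Rm, I
nr = NumericalResponse.from_rates(rates).fit()
fr = FunctionalResponse.from_rates(rates).fit()
print(nr.summary())
print(fr.summary())
```

prints

```
Threshold numerical response: mu = mu_max*(P-P')/(k2+P-P')
n = 24, RSS = 0.57047, AICc = -79.64
   param   estimate         SE        t          p
  mu_max     0.3779     0.0551     6.85      9e-07  [d^-1]
 p_prime     0.1068     0.0188     5.68    1.2e-05  [mg C/L]
      k2     0.1096     0.0386     2.84     0.0098  [mg C/L]
   alpha     3.4462     1.0589  [per (mg C/L) per d]

Functional response: Holling II (I = I_max*P/(k+P)) vs linear (I = slope*P)
n = 24; selected model: holling_II
  Holling II: I_max = 62.62 ± 29.4 ng C/cell/d, k = 11.01 ± 6.43 mg C/L, AICc = 19.37
  linear: slope = 4.476 ± 0.211 (ng C/cell/d)/(mg C/L), AICc = 21.29
```

One plate of 24 noisy endpoint counts is a genuinely hard estimation
problem: the NR threshold (0.107 vs truth 0.10 mg C/liter) is well
recovered while μ_max (0.378 ± 0.055 vs 0.45) and k₂ carry the
uncertainty the standard errors advertise; the FR is only weakly
saturated within the food range, so I_max is wide. Evaluating the fits
at the conventional moderate food level and converting to efficiency:

```python
mu, ing = float(nr.predict(0.5)), float(fr.predict(0.5))
gge = gross_growth_efficiency(mu, cell_biomass_ng=3.4, ingestion_ng_per_cell_d=ing)
print(mu, ing, gge.percent)   # 0.295 d^-1, 2.72 ng C/cell/d, 36.9 %
```

i.e. at 0.5 mg C/liter this simulated grazer grows at 0.30 d⁻¹, ingests
2.7 ng C cell⁻¹ d⁻¹ and converts ~37 % of ingested carbon into biomass.
`parameter_recovery_suite` repeats this loop over hundreds of plates and
reports bias, RMSE and confidence-interval coverage per parameter.

A CLI wraps the same pipeline:

```bash
nrfr simulate --seed 5 --out plate.csv --truth-out truth.json
nrfr rates plate.csv --out rates.csv
nrfr fit-nr rates.csv
nrfr fit-fr rates.csv
nrfr correct-bacteria rates.csv calibration.csv
nrfr report --input plate.csv --out report/
```

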