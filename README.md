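# debipm

A dynamic energy budget integral projection model (DEB-IPM) for bulb mite
(*Rhizoglyphus robini*) populations in fluctuating food environments, with
size-selective harvesting, coloured-noise food regimes, Markov-chain
stochastic demography and the bootstrap machinery needed to compare model
predictions against replicated laboratory census data.

It is written for population ecologists who want to go from a handful of
measurable life-history traits to population-level predictions — growth
rates, stage structure, harvest responses — and to test those predictions
against observed census tables.

## The model

The state is the number distribution `N(L, t)` of female body lengths
`L` (mm).  One day of dynamics is

```
N(L', t+1) = ∫_Ω [ D(L', L) R(L) + G(L', L) S(L) ] N(L, t) dL
```

with four trait-based functions driven by a dimensionless feeding level
`E(Y) ∈ (0, 1]` (empty to full gut):

* **Survival** `S(L) = exp(−μ)` up to the starvation bound
  `L_m·E(Y)/κ`, zero above it.
* **Growth** `G(L', L)`: Gaussian around the von Bertalanffy expectation
  `E[L'] = L e^(−r_B) + (1 − e^(−r_B)) L_∞` with plastic asymptote
  `L_∞ = L_m·E(Y)` and rate `r_B = 1/(151.0 − 137.8·L_∞)`; individuals
  shrink when food drops.
* **Reproduction** `R(L) = E(Y)·R_m·L²/L_m²` for mature females
  (`L ≥ L_p = 0.539·L_∞`), zero otherwise.
* **Inheritance** `D(L', L)`: newborns enter at the egg length
  `L_b = 0.166` mm.

Discretising `Ω = [0.9·L_b, L_m]` into 200 midpoint bins turns the kernel
into a daily projection matrix `A(E(Y))`; environments are sequences of
feeding levels (the experiment's 37 × 4-day coloured food series, or a
two-state good/bad Markov chain), and the long-run stochastic growth rate
is `log λ_s = (1/τ) Σ log(N_{t+1}/N_t)`.

Default parameters are the published bulb mite values (`L_b = 0.166` mm,
`L_m = 1.008` mm, `R_m = 16` female eggs/day, `κ = 0.083`, `μ = 0.03`/day,
`σ(Y) = 0.3`).

## Worked example

```python
import numpy as np
from debipm import DEBParams, HarvestRule, default_grid, run_experiment_simulation
from debipm.analysis import experiment_food_series

params = DEBParams()
grid = default_grid(params)
food = experiment_food_series(seed=0)["red"]   # strongly autocorrelated ration

unharvested = run_experiment_simulation(food, params, grid, ey_low=0.25, ey_high=0.45)
harvested = run_experiment_simulation(food, params, grid, rule=HarvestRule(),
                                      ey_low=0.25, ey_high=0.45)
print(round(unharvested.log_lambda_s, 4), round(harvested.log_lambda_s, 4))
```

prints

```
0.0548 0.0444
```

the daily log stochastic growth rates of an unharvested and a harvested
population over the 148-day red-noise food regime: both grow (positive
values), and removing 50% of the largest adults every 8th day costs about
0.01 per day in log growth.  The scripts in `examples/` walk through each
capability — kernel construction and the stationary feeding level,
building blue/white/red food series by spectral mimicry (lag-1
autocorrelations −0.873 / ~0 / +0.918 from the same 20-good/17-bad value
multiset), the full experiment replay above, the (p, q) Markov grid with
elasticities of λ_s, and a synthetic observed-census study run through the
bootstrap comparison pipeline — and print the numbers they compute with a
line on what they mean.

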