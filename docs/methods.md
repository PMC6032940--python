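# Methods

## Model

`debipm` implements a daily-time-step integral projection model whose
demographic functions come from dynamic energy budget (DEB) theory rather
than from regressions.  The state is the density `N(L, t)` of female body
lengths over a closed domain `Ω`; the kernel is the sum of a
survival–growth part `G(L', L) S(L)` and a reproduction–inheritance part
`D(L', L) R(L)`.  All environmental forcing passes through a single
scalar, the expected feeding level `E(Y) ∈ (0, 1]`:

* the growth asymptote `L_∞ = L_m E(Y)` and von Bertalanffy rate
  `r_B = 1/(151.0 − 137.8 L_∞)` (days⁻¹) both rise with food;
* the maturation threshold is plastic, `L_p = 0.539 L_∞`;
* reproduction is `R(L) = E(Y) R_m L²/L_m²` for mature, non-starving
  females;
* survival is a flat `exp(−μ)` per day up to the starvation bound
  `L_m E(Y)/κ`, zero above it, and starving sizes are also sterile (they
  would otherwise re-enter through the fecundity term).

Growth is Gaussian with standard deviation
`σ(L') = (1 − e^(−r_B)) L_m σ(Y)`, length-independent and increasing in
feeding level; lengths above the asymptote shrink toward it.  With the
default `σ_Lb = 0`, all offspring enter at exactly the egg length
`L_b`.

Assumptions worth keeping in mind: females only (a 1:1 genetic sex ratio
converts to mixed-sex counts); no density dependence beyond what the
feeding level encodes; no age structure, maternal effects or
juvenile–adult interference; the projection is deterministic given the
food sequence (environmental, not demographic, stochasticity).

## Parameters

| symbol | field | default | unit | meaning |
|---|---|---|---|---|
| L_b | `L_b` | 0.166 | mm | length at birth (egg length) |
| L_m | `L_m` | 1.008 | mm | maximum length at E(Y) = 1 |
| κ | `kappa` | 0.083 | – | assimilated-energy fraction to maintenance + growth; sets the starvation bound |
| μ | `mu` | 0.03 | d⁻¹ | background mortality rate |
| R_m | `R_m` | 16 | d⁻¹ | maximum female-offspring rate at L_m |
| σ(Y) | `sigma_Y` | 0.3 | – | SD of the feeding level (growth stochasticity) |
| – | `lp_coeff` | 0.539 | – | L_p as a fraction of L_∞ |
| – | `rb_c0`, `rb_c1` | 151.0, 137.8 | d, d·mm⁻¹ | growth-rate plasticity coefficients |
| – | `rb_scale` | 1.0 | – | multiplicative perturbation knob on r_B |
| σ_Lb | `sigma_Lb` | 0.0 | mm | SD of offspring length |

Defaults are the published bulb mite values and are reproduced exactly by
`DEBParams()`; parameter sets round-trip through flat YAML.

## Discretisation

`Ω = [0.9 L_b, L_m]`, 200 equal bins, midpoint rule; the lower margin
leaves room for growth mass just below the birth length.  Gaussian growth
mass falling outside `Ω` is truncated, not renormalised (loss < 0.1% at
the default parameters; renormalising would silently raise survival).
With `σ_Lb = 0` the newborn column is an exact unit mass in the bin
containing `L_b`, never a numerically evaluated delta.

Two numerical caveats follow from the narrow growth kernel:

* **Low-feeding aliasing.**  The growth SD falls below the bin width for
  `E(Y) ≲ 0.3` (e.g. 0.0023 mm vs 0.0043 mm at E(Y) = 0.15), and midpoint
  sums of the Gaussian then deviate from 1 by up to ~1% (they explode on
  much coarser meshes — a 50-bin mesh is unusable).  Mass-conservation
  checks are therefore asserted at `E(Y) ≥ 0.36`; results at very low
  feeding levels carry this extra quadrature error.  200 bins is the
  package default and `n_bins` is configurable.
* **Birth-size staircase.**  Because newborns occupy a single bin, any
  quantity differentiated with respect to `L_b` at sub-bin resolution is a
  step function.  The elasticity of λ_s to a 1% change in `L_b`
  (0.0017 mm, less than half a bin) is resolution-limited and should not
  be over-interpreted; the other six elasticities are smooth (forward and
  backward 1% perturbations agree within 25%).

The fecundity term implements the kernel literally as `D R + G S` by
default; a `fecundity_survival_weighted` flag multiplies `R` by the
parent's survival for the reading in which only surviving adults
reproduce.  The two variants move the dominant eigenvalue by less than
0.5% everywhere (their stationary feeding levels are 0.0975 and 0.0993),
so nothing downstream depends on the choice.

## Environments

The experimental regime is a 37-step series of 4-day blocks at 2 or 8
yeast rods/day (20 good, 17 bad — the unique two-valued composition whose
mean and sample variance round to 5.24 and 9.19; the sample convention
with denominator n−1 is used throughout).  Recolouring is by spectral
mimicry — the series is permuted so its rank order follows a surrogate,
preserving the value multiset exactly — with AR(1)(±0.95) and
alternating/sorted surrogates as starts, refined by steepest-ascent
pairwise-swap hill climbing on the lag-1 autocorrelation.  The attainable
extremes for this series are ρ₁ ≈ −0.873 (blue) and +0.918 (red); series
of length ≤ 8 are solved exhaustively.  The 5-rod control ration has no
stated feeding-level equivalent and maps to the midpoint of
(`ey_low`, `ey_high`) by default (configurable).

The generalised environment is a two-state daily Markov chain: `p` is the
good→bad switching probability, `q` the bad→good one, autocorrelation
`ρ = 1 − p − q`, good-state frequency `f = q/(p+q)`, with
`E(Y)_good = 0.60` and `E(Y)_bad = 0.15` as defaults.  The chain switches
daily even though the experiment fed in 4-day blocks.

## Simulations

The experiment replay starts 20 founder adults in the bin nearest
`L_∞(ey_mid)` (founders were raised on the control ration; a uniform
placement over adult bins is available), acclimates 31 days on the control
ration, then runs 148 days on the daily expansion of a food series.
Censuses are taken post-projection every 4th day (37 records); on every
8th day the harvested treatment removes, after the census, 50% of adults
longer than 1.0235 × the current abundance-weighted mean adult length.
`log λ_s` averages the 148 daily log growth ratios (telescoping makes it
`log(N_end/N_start)/τ`).  Founder removal, which the real experiment
performed after 7–9 days, is not modelled and is a known caveat for
prediction–observation comparisons.

The stochastic demographic model projects one individual per size bin
through a 3,000-day chain sample (initial state uniform), discards a
500-day transient, and averages the remaining τ = 2,500 daily log ratios;
the abundance vector is renormalised daily so long runs neither overflow
nor underflow.  Elasticities perturb one parameter at a time by +1%
(forward differences, matching the stated procedure) under a common
environment path, on `λ_s = exp(log λ_s)`; maturation is perturbed via
`lp_coeff` and the growth rate via `rb_scale` so each perturbation stays
one-dimensional.  Whether base and perturbed runs should share the
environment path was an open choice; common random numbers were chosen
because they remove path noise from a difference of ~10⁻³.

Stage counts: the egg stage is not a size class, so two conventions are
implemented and neither is privileged — a cutoff mode (bins up to 0.2 mm
count as eggs) and a production mode (the day's egg output `Σ R(L) n(L)`).
Because `L_p` is plastic it falls below the egg cutoff for
`E(Y) < 0.37` (and below `L_b` itself for `E(Y) < 0.305`); maturity takes
precedence, so at low food the entire population can count as adult and
the egg/juvenile classes are legitimately empty.

## Comparison machinery

Observed census tables (CSV; colour, harvest, tube, day, eggs, juveniles,
adults) are mixed-sex integer counts; halving converts them to
model-comparable female counts.  Confidence intervals use a stratified
BCa bootstrap (default 1,000 resamples within tubes, preserving tube
sizes; bias correction from the bootstrap distribution, acceleration from
the jackknife skewness over all observations), cross-checked against an
independent BCa implementation in the test suite, with ~95% empirical
coverage at n = 100.  A prediction is "consistent" with an observation
when it lies inside (or, for intervals, intersects) the closed observed
interval.

The synthetic-data generator emulates the experiment's structure —
treatments × 3 replicate tubes × 37 censuses, the half-female sex
convention, multiplicative lognormal observation noise (σ_log = 0.2
default, Poisson available) with per-tube sub-seeds, integer rounding,
and a dropped-tube scenario for unbalanced strata.  It deliberately does
not emulate juvenile–adult interference competition, founder removal or
any density feedback the kernel lacks, so passing recovery tests shows
the *pipeline* is self-consistent, not that the model captures those
features of real populations.

## Calibration finding and known limitations

A faithful implementation of the published equations and parameter values
is **supercritical across the entire experimental feeding range**: the
200-bin kernel's dominant eigenvalue exceeds 1 everywhere on
E(Y) ∈ [0.10, 0.90], and the population is stationary only near
E(Y) ≈ 0.10 (0.0975 literal, 0.0993 survival-weighted).  This was verified
against an independent deterministic-cohort Euler–Lotka calculation and at
800 bins, so it is a property of the equations, not of the code or mesh.
The driver is the plastic maturation threshold: at E(Y) = 0.36 a newborn
matures in ~16 days and then produces ~0.75 female eggs/day against a
3%/day mortality, giving a lifetime reproduction far above replacement —
and for E(Y) < 0.305 the threshold sinks below the birth length entirely,
so newborns are born mature and even meagre rations sustain growth.

Empirical work on this laboratory system reports population stationarity
near E(Y) ≈ 0.36, with decline below and growth above.  That behaviour is
not reproducible from these equations: there is no zero contour of
`log λ_s` inside the experimental feeding ranges, the eigenvalue is not
monotone in E(Y) below ~0.45 (it peaks where `L_p` crosses `L_b` and dips
to a local minimum near 0.42), log λ_s is U-shaped rather than increasing
in the good-state frequency `f`, and the elasticity landscape is dominated
by `L_b` and `lp_coeff` rather than shifting μ → L_p → L_m with rising
growth.  Reconciling the two would require an additional mortality or
fecundity-reduction mechanism (roughly a six-fold effective fecundity
reduction at E(Y) = 0.36) that the published equations do not contain;
rather than tune one in, the package implements the equations as stated
and documents the discrepancy here.  Users calibrating to their own data
can reach every relevant quantity through `DEBParams`.
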