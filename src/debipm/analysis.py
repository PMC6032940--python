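"""Population-level analyses: the cross-level feeding-level sweep, the
two-state Markov stochastic demography with elasticities, and the
stratified BCa bootstrap used to put confidence intervals on observed
census summaries.

The cross-level sweep replays the harvesting experiment over a grid of
assumed (EY_low, EY_high) feeding-level pairs, because the feeding levels
actually experienced by the experimental populations are unknown; each
cell records the stochastic growth rate and mean log stage counts so they
can be compared with observed confidence intervals.

The stochastic demographic model draws a daily good/bad environment path
from the Markov chain, projects one individual per size bin through 3,000
days, discards a 500-day transient, and averages the remaining 2,500 daily
log growth ratios into log lambda_s.  Elasticities perturb one life-history
parameter at a time by 1% under a common environment path.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from debipm.core import (
    DEBParams,
    SizeGrid,
    build_kernel,
    default_grid,
)
from debipm.environment import (
    FoodSeries,
    MarkovEnvironment,
    make_white_series,
    markov_stats,
    optimise_autocorrelation,
    sample_markov_states,
)
from debipm.population import (
    NO_HARVEST,
    HarvestRule,
    PopulationState,
    apply_harvest,
    log_stochastic_growth_rate,
    run_experiment_simulation,
)

__all__ = [
    "crosslevel_sweep",
    "experiment_food_series",
    "stochastic_lambda",
    "stochastic_grid",
    "elasticity",
    "ELASTICITY_PARAMETERS",
    "CIRecord",
    "bootstrap_bca",
    "overlap_test",
]

_LOG_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# cross-level sweep


def experiment_food_series(seed: int = 0) -> dict:
    """The three coloured 37-step food series sharing one white draw.

    Blue and red are autocorrelation-extremised permutations of the white
    series (spectral mimicry starts refined by pairwise-swap search), as in
    the experiment where all colours shared identical value distributions.
    """
    white = make_white_series(seed=seed)
    blue, _ = optimise_autocorrelation(white, "minimize", seed=seed)
    red, _ = optimise_autocorrelation(white, "maximize", seed=seed)
    return {"blue": blue, "white": white, "red": red}


def crosslevel_sweep(
    params: DEBParams,
    grid: SizeGrid,
    food_series: dict | None = None,
    ey_low_values=None,
    ey_high_values=None,
    harvest_rule: HarvestRule = HarvestRule(),
    seed: int = 0,
    **sim_kwargs,
) -> pd.DataFrame:
    """Replay the experiment over a grid of assumed feeding-level pairs.

    Returns a long-format table with one row per
    (colour, harvest, EY_low, EY_high) cell carrying ``log_lambda_s`` and
    the mean log-transformed stage counts over the 37 censuses of the
    experimental period.  Default resolution is 26 x 25 over
    ``0.10 <= EY_low < 0.36`` and ``0.36 <= EY_high <= 0.60``.
    """
    if food_series is None:
        food_series = experiment_food_series(seed=seed)
    if ey_low_values is None:
        ey_low_values = np.linspace(0.10, 0.35, 26)
    if ey_high_values is None:
        ey_high_values = np.linspace(0.36, 0.60, 25)
    rows = []
    for colour, food in food_series.items():
        for harvested in (False, True):
            rule = harvest_rule if harvested else NO_HARVEST
            for ey_low, ey_high in itertools.product(
                ey_low_values, ey_high_values
            ):
                if ey_low >= ey_high:
                    continue
                res = run_experiment_simulation(
                    food,
                    params,
                    grid,
                    rule=rule,
                    ey_low=float(ey_low),
                    ey_high=float(ey_high),
                    **sim_kwargs,
                )
                frame = res.census_frame()
                extinct = bool((frame["total"] <= 0).any()) or not np.isfinite(
                    res.log_lambda_s
                )
                rows.append(
                    {
                        "colour": colour,
                        "harvest": harvested,
                        "ey_low": float(ey_low),
                        "ey_high": float(ey_high),
                        "log_lambda_s": res.log_lambda_s,
                        "mean_log_eggs": float(
                            np.log(np.maximum(frame["eggs"], _LOG_FLOOR)).mean()
                        ),
                        "mean_log_juveniles": float(
                            np.log(np.maximum(frame["juveniles"], _LOG_FLOOR)).mean()
                        ),
                        "mean_log_adults": float(
                            np.log(np.maximum(frame["adults"], _LOG_FLOOR)).mean()
                        ),
                        "extinct": extinct,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stochastic demography


def _project_states(
    states: np.ndarray,
    env: MarkovEnvironment,
    params: DEBParams,
    grid: SizeGrid,
    rule: HarvestRule,
    burn_in: int,
    fecundity_survival_weighted: bool = False,
) -> float:
    """log lambda_s along a fixed good/bad state path.

    Starts from one individual per size bin and renormalises daily so long
    runs neither overflow nor underflow.
    """
    kernels = {
        ey: build_kernel(ey, grid, params, fecundity_survival_weighted).matrix
        for ey in (env.ey_good, env.ey_bad)
    }
    v = np.ones(grid.n_bins)
    log_growth = np.empty(len(states))
    for t, good in enumerate(states):
        ey = env.ey_good if good else env.ey_bad
        v = kernels[ey] @ v
        if rule.enabled and (t + 1) % rule.interval_days == 0:
            state = apply_harvest(
                PopulationState(v, grid), rule, ey, params
            )
            v = state.abundances
        total = v.sum()
        if total <= 0:
            raise FloatingPointError("population went extinct along this path")
        log_growth[t] = np.log(total)
        v = v / total
    return float(log_growth[burn_in:].mean())


def stochastic_lambda(
    env: MarkovEnvironment,
    params: DEBParams,
    grid: SizeGrid | None = None,
    rule: HarvestRule = NO_HARVEST,
    length: int = 3000,
    burn_in: int = 500,
    seed: int | None = None,
    fecundity_survival_weighted: bool = False,
) -> dict:
    """Long-run stochastic growth rate under the two-state Markov chain.

    Samples a state path of *length* days (initial state uniform), projects
    one individual per size bin, discards the first *burn_in* daily growth
    ratios and averages the remaining ``tau = length - burn_in`` into
    ``log_lambda_s``.
    """
    if length <= burn_in:
        raise ValueError("length must exceed burn_in")
    if grid is None:
        grid = default_grid(params)
    states = sample_markov_states(env, length, seed)
    log_lambda = _project_states(
        states, env, params, grid, rule, burn_in, fecundity_survival_weighted
    )
    rho, f = markov_stats(env)
    return {
        "log_lambda_s": log_lambda,
        "tau": length - burn_in,
        "rho": rho,
        "f": f,
    }


def stochastic_grid(
    p_values,
    q_values,
    params: DEBParams,
    grid: SizeGrid | None = None,
    rule: HarvestRule = NO_HARVEST,
    ey_good: float = 0.60,
    ey_bad: float = 0.15,
    length: int = 3000,
    burn_in: int = 500,
    seed: int | None = None,
) -> pd.DataFrame:
    """log lambda_s over a (p, q) grid of Markov environments.

    Each cell is annotated with its autocorrelation ``rho`` and good-state
    frequency ``f``; cells share the seed stream deterministically so
    harvested/unharvested comparisons can reuse identical paths.
    """
    if grid is None:
        grid = default_grid(params)
    rows = []
    for i, p in enumerate(p_values):
        for j, q in enumerate(q_values):
            env = MarkovEnvironment(p=float(p), q=float(q), ey_good=ey_good, ey_bad=ey_bad)
            cell_seed = None if seed is None else int(seed) + 1000 * i + j
            out = stochastic_lambda(
                env, params, grid, rule, length, burn_in, cell_seed
            )
            rows.append({"p": float(p), "q": float(q), **out, "seed": cell_seed})
    return pd.DataFrame(rows)


ELASTICITY_PARAMETERS = ("L_b", "lp_coeff", "L_m", "R_m", "rb_scale", "kappa", "mu")


def elasticity(
    env: MarkovEnvironment,
    params: DEBParams,
    grid: SizeGrid | None = None,
    rule: HarvestRule = NO_HARVEST,
    delta: float = 0.01,
    length: int = 3000,
    burn_in: int = 500,
    seed: int | None = None,
    parameters=ELASTICITY_PARAMETERS,
) -> dict:
    """Elasticity of lambda_s to a 1% perturbation of each parameter.

    Forward differences on ``lambda_s = exp(log_lambda_s)`` with common
    random numbers: base and perturbed runs share the same environment
    path.  Maturation enters through its proportionality coefficient and
    the growth rate through a multiplicative scale, so each perturbation
    stays one-dimensional.  Returns the per-parameter elasticities plus the
    parameter with the largest absolute elasticity.
    """
    if grid is None:
        grid = default_grid(params)
    states = sample_markov_states(env, length, seed)
    base_log = _project_states(states, env, params, grid, rule, burn_in)
    base = float(np.exp(base_log))
    out = {"log_lambda_s": base_log, "elasticity": {}}
    for name in parameters:
        perturbed = params.replace(**{name: getattr(params, name) * (1.0 + delta)})
        pert_log = _project_states(states, env, perturbed, grid, rule, burn_in)
        out["elasticity"][name] = (np.exp(pert_log) - base) / (delta * base)
    out["argmax"] = max(out["elasticity"], key=lambda k: abs(out["elasticity"][k]))
    return out


# ---------------------------------------------------------------------------
# stratified BCa bootstrap and the CI-overlap comparison


@dataclass(frozen=True)
class CIRecord:
    """Point estimate with a BCa bootstrap confidence interval."""

    estimate: float
    lower: float
    upper: float
    n_resamples: int
    strata: tuple = ()
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.lower <= self.estimate <= self.upper:
            raise ValueError("CI bounds must bracket the estimate")


def bootstrap_bca(
    values,
    strata=None,
    statistic=np.mean,
    n_resamples: int = 1000,
    confidence: float = 0.95,
    seed: int | None = None,
) -> CIRecord:
    """Stratified bias-corrected and accelerated (BCa) bootstrap interval.

    Resampling is with replacement *within* strata, preserving stratum
    sizes (the experiment's replicate tubes).  The bias correction ``z0``
    comes from the bootstrap distribution's position relative to the point
    estimate and the acceleration ``a`` from the jackknife skewness.  A
    degenerate bootstrap distribution collapses to a point interval.
    """
    x = np.asarray(values, dtype=float)
    if strata is None:
        strata = np.zeros(len(x), dtype=int)
    strata = np.asarray(strata)
    if strata.shape != x.shape:
        raise ValueError("strata labels must match values")
    labels = np.unique(strata)
    groups = [np.flatnonzero(strata == lab) for lab in labels]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each stratum needs at least 2 values to resample")

    rng = np.random.default_rng(seed)
    theta_hat = float(statistic(x))

    # resample indices within each stratum, preserving stratum sizes
    idx = np.concatenate(
        [g[rng.integers(0, len(g), size=(n_resamples, len(g)))] for g in groups],
        axis=1,
    )
    try:  # vectorised statistics (mean, median, ...) evaluate row-wise
        boot = np.asarray(statistic(x[idx], axis=-1), dtype=float)
        if boot.shape != (n_resamples,):
            raise TypeError
    except TypeError:
        boot = np.array([statistic(x[row]) for row in idx])

    if np.ptp(boot) == 0.0 and boot[0] == theta_hat:
        return CIRecord(
            theta_hat, theta_hat, theta_hat, n_resamples, tuple(labels), degenerate=True
        )

    # bias correction: clip so a bootstrap distribution entirely on one
    # side of the estimate still yields a finite z0
    prop = np.clip(
        np.mean(boot < theta_hat), 1.0 / (2 * n_resamples), 1 - 1.0 / (2 * n_resamples)
    )
    z0 = stats.norm.ppf(prop)

    # jackknife acceleration (leave-one-out over all observations)
    jack = np.array(
        [statistic(np.delete(x, i)) for i in range(len(x))]
    )
    d = jack.mean() - jack
    denom = (d @ d) ** 1.5
    a = float((d**3).sum() / (6.0 * denom)) if denom > 0 else 0.0

    alpha = 1.0 - confidence
    z = stats.norm.ppf([alpha / 2, 1 - alpha / 2])
    adj = stats.norm.cdf(z0 + (z0 + z) / (1.0 - a * (z0 + z)))
    lower, upper = np.quantile(boot, adj)
    lower = min(lower, theta_hat)
    upper = max(upper, theta_hat)
    return CIRecord(
        theta_hat, float(lower), float(upper), n_resamples, tuple(labels)
    )


def overlap_test(observed: CIRecord, predicted) -> bool:
    """Whether a prediction is consistent with an observed interval.

    *predicted* may be a point value (consistent if inside the closed
    observed interval) or another ``CIRecord`` / ``(lower, upper)`` pair
    (consistent if the closed intervals intersect, touching endpoints
    included).
    """
    if isinstance(predicted, CIRecord):
        lo, hi = predicted.lower, predicted.upper
    elif np.iterable(predicted):
        lo, hi = map(float, predicted)
    else:
        lo = hi = float(predicted)
    return lo <= observed.upper and hi >= observed.lower
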