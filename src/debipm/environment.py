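"""Food environments: the experimental coloured-noise food series and the
two-state Markov environment.

The laboratory experiment fed mites 2 (bad) or 8 (good) yeast rods per day
in 37 blocks of 4 days.  A white series is a random permutation of 20
eights and 17 twos; red and blue series are *permutations of the same
values* whose rank order follows an autocorrelated surrogate (spectral
mimicry), so mean, min, max and variance are identical across colours and
only the temporal structure differs.

The generalised stochastic environment is a two-state Markov chain with
daily switching probabilities ``p`` (good to bad) and ``q`` (bad to good);
its lag-1 autocorrelation is ``rho = 1 - p - q`` and the stationary
frequency of the good state is ``f = q / (p + q)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FoodSeries",
    "MarkovEnvironment",
    "EnvironmentSequence",
    "N_STEPS",
    "DAYS_PER_STEP",
    "RODS_LOW",
    "RODS_HIGH",
    "RODS_MID",
    "make_white_series",
    "lag1_autocorrelation",
    "spectral_mimicry",
    "ar1_surrogate",
    "optimise_autocorrelation",
    "rods_to_feeding",
    "expand_to_daily",
    "markov_stats",
    "sample_markov_sequence",
]

N_STEPS = 37
DAYS_PER_STEP = 4
RODS_LOW, RODS_MID, RODS_HIGH = 2, 5, 8


@dataclass(frozen=True)
class FoodSeries:
    """A 37-step food time series of daily yeast-rod rations.

    Each step spans 4 days; values are 2 (bad) or 8 (good) rods per day,
    except the constant control series which uses 5 throughout.
    """

    rods_per_step: tuple
    colour_label: str = "white"
    days_per_step: int = DAYS_PER_STEP

    def __post_init__(self) -> None:
        rods = tuple(int(r) for r in self.rods_per_step)
        object.__setattr__(self, "rods_per_step", rods)
        if len(rods) != N_STEPS:
            raise ValueError(f"food series must have {N_STEPS} steps")
        allowed = {RODS_MID} if self.colour_label == "constant" else {RODS_LOW, RODS_HIGH}
        if not set(rods) <= allowed:
            raise ValueError(
                f"{self.colour_label} series may only contain values {sorted(allowed)}"
            )

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.rods_per_step, dtype=float)

    @property
    def total_days(self) -> int:
        return len(self.rods_per_step) * self.days_per_step

    def save(self, path, seed=None) -> None:
        """Two-column text (step, rods) with a metadata comment header."""
        rho = (
            lag1_autocorrelation(self.values)
            if self.colour_label != "constant"
            else float("nan")
        )
        header = f"colour={self.colour_label} seed={seed} rho={rho:.4f}"
        data = np.column_stack([np.arange(N_STEPS), self.values])
        np.savetxt(path, data, fmt="%d", header=header)


def constant_series() -> FoodSeries:
    """The control ration: five rods per day for the whole experiment."""
    return FoodSeries((RODS_MID,) * N_STEPS, colour_label="constant")


def make_white_series(
    n_high: int = 20, n_low: int = 17, seed: int | None = None
) -> FoodSeries:
    """Uniformly random arrangement of *n_high* eights and *n_low* twos.

    The 20/17 composition is the unique one whose mean (5.24) and sample
    variance (9.19) match the experimental series.
    """
    if n_high + n_low != N_STEPS:
        raise ValueError(f"n_high + n_low must equal {N_STEPS}")
    rng = np.random.default_rng(seed)
    rods = np.array([RODS_HIGH] * n_high + [RODS_LOW] * n_low)
    rng.shuffle(rods)
    return FoodSeries(tuple(rods), colour_label="white")


def lag1_autocorrelation(series) -> float:
    """Sample lag-1 autocorrelation.

    Deviations are taken from the overall series mean and the denominator
    is the total sum of squares, i.e. the standard sample ACF estimator
    ``r1 = sum (x_t - xbar)(x_{t+1} - xbar) / sum (x_t - xbar)^2``.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    d = x - x.mean()
    ss = float(d @ d)
    if ss == 0.0:
        raise ValueError("lag-1 autocorrelation undefined for a constant series")
    return float(d[:-1] @ d[1:]) / ss


def _as_values(series) -> tuple[np.ndarray, str]:
    if isinstance(series, FoodSeries):
        return series.values, series.colour_label
    return np.asarray(series, dtype=float), "white"


def spectral_mimicry(series, surrogate, colour_label: str | None = None):
    """Permutation of *series* whose rank order matches *surrogate*.

    The k-th smallest value of the series is placed at the position of the
    k-th smallest surrogate value (ties in the surrogate broken by index,
    so ``spectral_mimicry(x, x) == x``).  The multiset of values — hence
    mean, min, max and variance — is preserved exactly; only the temporal
    arrangement, and so the autocorrelation, changes.
    """
    values, label = _as_values(series)
    surrogate = np.asarray(surrogate, dtype=float)
    if surrogate.shape != values.shape:
        raise ValueError("surrogate must have the same length as the series")
    order = np.argsort(surrogate, kind="stable")
    out = np.empty_like(values)
    out[order] = np.sort(values, kind="stable")
    if isinstance(series, FoodSeries):
        return FoodSeries(tuple(out.astype(int)), colour_label or label)
    return out


def ar1_surrogate(n: int, phi: float, seed: int | None = None) -> np.ndarray:
    """First-order autoregressive surrogate with coefficient *phi*."""
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = eps[0] / np.sqrt(max(1.0 - phi**2, 1e-12))
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x


def _hill_climb(values: np.ndarray, sign: float) -> tuple[np.ndarray, float]:
    """Steepest-ascent pairwise-swap search on ``sign * r1``."""
    x = values.copy()
    best = sign * lag1_autocorrelation(x)
    improved = True
    while improved:
        improved = False
        n = len(x)
        best_swap, best_val = None, best
        for i in range(n - 1):
            for j in range(i + 1, n):
                if x[i] == x[j]:
                    continue
                x[i], x[j] = x[j], x[i]
                val = sign * lag1_autocorrelation(x)
                x[i], x[j] = x[j], x[i]
                if val > best_val:
                    best_swap, best_val = (i, j), val
        if best_swap is not None:
            i, j = best_swap
            x[i], x[j] = x[j], x[i]
            best = best_val
            improved = True
    return x, sign * best


def optimise_autocorrelation(
    series,
    direction: str = "minimize",
    n_restarts: int = 10,
    seed: int | None = None,
):
    """Extremal lag-1 autocorrelation attainable by permuting *series*.

    Pairwise-swap hill climbing from rank-matched starts: an alternating
    (minimise) or sorted (maximise) surrogate plus AR(1) surrogates with
    coefficient -0.95 / +0.95.  For series of length <= 8 the optimum is
    found by exhaustive enumeration instead.  Returns ``(series, rho)``.
    """
    if direction not in ("minimize", "maximize"):
        raise ValueError("direction must be 'minimize' or 'maximize'")
    values, label = _as_values(series)
    sign = -1.0 if direction == "minimize" else 1.0
    n = len(values)

    if n <= 8:
        best, best_val = None, -np.inf
        for perm in set(itertools.permutations(values)):
            val = sign * lag1_autocorrelation(np.array(perm))
            if val > best_val:
                best, best_val = np.array(perm), val
        result, rho = best, sign * best_val
    else:
        rng = np.random.default_rng(seed)
        if direction == "minimize":
            starts = [np.where(np.arange(n) % 2 == 0, 1.0, -1.0)]
            phi = -0.95
        else:
            starts = [np.arange(n, dtype=float)]
            phi = 0.95
        starts += [
            ar1_surrogate(n, phi, int(rng.integers(2**31)))
            for _ in range(max(n_restarts - 1, 0))
        ]
        best, best_val = None, -np.inf
        for surrogate in starts:
            x0 = spectral_mimicry(values, surrogate)
            x, rho_x = _hill_climb(x0, sign)
            if sign * rho_x > best_val:
                best, best_val = x, sign * rho_x
        result, rho = best, sign * best_val

    if isinstance(series, FoodSeries):
        colour = "blue" if direction == "minimize" else "red"
        return FoodSeries(tuple(result.astype(int)), colour), rho
    return result, rho


def rods_to_feeding(
    rods: int, ey_low: float, ey_high: float, ey_mid: float | None = None
) -> float:
    """Map a daily rod ration to its assumed feeding level E(Y).

    2 rods -> *ey_low*, 8 rods -> *ey_high*; the 5-rod control ration maps
    to *ey_mid*, by default the midpoint of the two (its feeding-level
    equivalent was never measured, so this is an explicit assumption).
    """
    if ey_mid is None:
        ey_mid = 0.5 * (ey_low + ey_high)
    mapping = {RODS_LOW: ey_low, RODS_MID: ey_mid, RODS_HIGH: ey_high}
    try:
        return float(mapping[int(rods)])
    except KeyError:
        raise ValueError(f"rod count must be one of {sorted(mapping)}, got {rods}")


@dataclass(frozen=True)
class EnvironmentSequence:
    """Daily feeding levels driving the projection, with provenance."""

    daily_ey: np.ndarray
    source: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        ey = np.asarray(self.daily_ey, dtype=float)
        object.__setattr__(self, "daily_ey", ey)
        if np.any((ey <= 0) | (ey > 1)):
            raise ValueError("all feeding levels must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.daily_ey)

    def save(self, path) -> None:
        header = f"source={self.source} seed={self.seed}"
        data = np.column_stack([np.arange(len(self)), self.daily_ey])
        np.savetxt(path, data, fmt=["%d", "%.6f"], header=header)


def expand_to_daily(
    series: FoodSeries,
    ey_low: float,
    ey_high: float,
    ey_mid: float | None = None,
) -> EnvironmentSequence:
    """Repeat each 4-day block's feeding level for its 4 days (148 total)."""
    daily = np.repeat(
        [rods_to_feeding(r, ey_low, ey_high, ey_mid) for r in series.rods_per_step],
        series.days_per_step,
    )
    return EnvironmentSequence(daily, source=f"food:{series.colour_label}")


@dataclass(frozen=True)
class MarkovEnvironment:
    """Two-state (good/bad) daily Markov chain environment.

    ``p`` is the daily probability of switching good -> bad and ``q`` of
    bad -> good.
    """

    p: float
    q: float
    ey_good: float = 0.60
    ey_bad: float = 0.15

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 and 0.0 <= self.q <= 1.0):
            raise ValueError("switching probabilities must lie in [0, 1]")
        if not self.ey_bad < self.ey_good:
            raise ValueError("ey_bad must be below ey_good")

    @property
    def transition_matrix(self) -> np.ndarray:
        """Column-stochastic matrix over (good, bad) states."""
        return np.array([[1.0 - self.p, self.q], [self.p, 1.0 - self.q]])


def markov_stats(env: MarkovEnvironment) -> tuple[float, float]:
    """Autocorrelation ``rho = 1 - p - q`` and good-state frequency
    ``f = q / (p + q)``."""
    rho = 1.0 - env.p - env.q
    if env.p + env.q == 0.0:
        raise ValueError("good-state frequency undefined for p = q = 0")
    return rho, env.q / (env.p + env.q)


def sample_markov_states(
    env: MarkovEnvironment, length: int, seed: int | None = None
) -> np.ndarray:
    """Boolean state path (True = good), initial state uniform."""
    if length < 1:
        raise ValueError("length must be at least 1")
    rng = np.random.default_rng(seed)
    u = rng.random(length)
    states = np.empty(length, dtype=bool)
    states[0] = u[0] < 0.5
    for t in range(1, length):
        if states[t - 1]:
            states[t] = u[t] >= env.p
        else:
            states[t] = u[t] < env.q
    return states


def sample_markov_sequence(
    env: MarkovEnvironment, length: int, seed: int | None = None
) -> EnvironmentSequence:
    """Daily feeding-level sequence from the two-state chain."""
    states = sample_markov_states(env, length, seed)
    daily = np.where(states, env.ey_good, env.ey_bad)
    return EnvironmentSequence(
        daily, source=f"markov:p={env.p},q={env.q}", seed=seed
    )
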