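"""Synthetic "observed" census tables with the structure of the mite
harvesting experiment.

The generator runs the deterministic DEB-IPM simulation for each treatment
(noise colour x harvest), converts female stage counts to observed
conventions — adult counts are mixed-sex, i.e. twice the model's females,
and eggs/juveniles are total counts of which half are assigned female on
read-back — then applies per-tube multiplicative lognormal observation
noise and rounds to integer counts.  Three replicate tubes per treatment,
censused every fourth day over the 148-day experiment, emulate the
experimental design; real biology the model omits (juvenile-adult
interference, founder removal) is deliberately not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from debipm.core import DEBParams, SizeGrid, default_grid
from debipm.environment import FoodSeries, constant_series, make_white_series, optimise_autocorrelation
from debipm.population import (
    NO_HARVEST,
    HarvestRule,
    SimulationResult,
    run_experiment_simulation,
)

__all__ = [
    "SyntheticStudyConfig",
    "CENSUS_COLUMNS",
    "generate_study",
    "write_census_table",
    "read_census_table",
    "to_female_counts",
    "drop_tube",
]

CENSUS_COLUMNS = ["colour", "harvest", "tube", "day", "eggs", "juveniles", "adults"]


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Design and noise settings for one synthetic study."""

    ey_low: float = 0.25
    ey_high: float = 0.45
    ey_mid: float | None = None
    n_tubes: int = 3
    colours: tuple = ("constant", "blue", "white", "red")
    harvests: tuple = (False, True)
    noise_sd: float = 0.2       # s.d. of log multiplicative count error
    noise_model: str = "lognormal"  # or "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tubes < 1:
            raise ValueError("need at least one tube per treatment")
        if self.noise_sd < 0:
            raise ValueError("noise s.d. must be non-negative")
        if self.noise_model not in ("lognormal", "poisson"):
            raise ValueError("noise_model must be 'lognormal' or 'poisson'")


def _food_series(config: SyntheticStudyConfig) -> dict:
    series = {}
    white = make_white_series(seed=config.seed)
    for colour in config.colours:
        if colour == "constant":
            series[colour] = constant_series()
        elif colour == "white":
            series[colour] = white
        elif colour in ("blue", "red"):
            direction = "minimize" if colour == "blue" else "maximize"
            series[colour], _ = optimise_autocorrelation(
                white, direction, seed=config.seed
            )
        else:
            raise ValueError(f"unknown colour {colour!r}")
    return series


def simulate_truth(
    config: SyntheticStudyConfig,
    params: DEBParams,
    grid: SizeGrid | None = None,
) -> dict:
    """Noise-free treatment trajectories underlying a study.

    Returns ``{(colour, harvested): SimulationResult}`` keyed by treatment.
    """
    if grid is None:
        grid = default_grid(params)
    out = {}
    for colour, food in _food_series(config).items():
        for harvested in config.harvests:
            rule = HarvestRule() if harvested else NO_HARVEST
            out[(colour, harvested)] = run_experiment_simulation(
                food,
                params,
                grid,
                rule=rule,
                ey_low=config.ey_low,
                ey_high=config.ey_high,
                ey_mid=config.ey_mid,
            )
    return out


def generate_study(
    config: SyntheticStudyConfig,
    params: DEBParams,
    grid: SizeGrid | None = None,
    truth: dict | None = None,
) -> pd.DataFrame:
    """Mock observed census table for a full study.

    Observed counts are mixed-sex (model female counts doubled), perturbed
    per tube by the configured observation-noise model and rounded to
    integers.  Tube noise streams are sub-seeded so tubes are independent
    replicates of the same deterministic trajectory.
    """
    if truth is None:
        truth = simulate_truth(config, params, grid)
    rng = np.random.default_rng(config.seed)
    rows = []
    for (colour, harvested), result in truth.items():
        frame = result.census_frame()
        observed_truth = frame[["eggs", "juveniles", "adults"]].to_numpy() * 2.0
        for tube in range(1, config.n_tubes + 1):
            tube_rng = np.random.default_rng(rng.integers(2**31))
            if config.noise_sd == 0.0 and config.noise_model == "lognormal":
                noisy = observed_truth
            elif config.noise_model == "lognormal":
                factors = np.exp(
                    tube_rng.normal(0.0, config.noise_sd, observed_truth.shape)
                )
                noisy = observed_truth * factors
            else:
                noisy = tube_rng.poisson(observed_truth).astype(float)
            counts = np.rint(np.clip(noisy, 0, 2**62)).astype(np.int64)
            for (day, *_), (eggs, juv, adults) in zip(
                frame.itertuples(index=False), counts
            ):
                rows.append(
                    {
                        "colour": colour,
                        "harvest": bool(harvested),
                        "tube": tube,
                        "day": int(day),
                        "eggs": int(eggs),
                        "juveniles": int(juv),
                        "adults": int(adults),
                    }
                )
    return pd.DataFrame(rows, columns=CENSUS_COLUMNS)


def to_female_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Convert observed mixed-sex counts to model-comparable female counts.

    Half of all eggs and juveniles are assigned female (the species' 1:1
    genetic sex ratio) and adult counts are halved likewise.
    """
    out = table.copy()
    for col in ("eggs", "juveniles", "adults"):
        out[col] = out[col] / 2.0
    return out


def write_census_table(table: pd.DataFrame, path) -> None:
    """Write a census table as comma-separated text with a fixed header."""
    missing = [c for c in CENSUS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns {missing}")
    table[CENSUS_COLUMNS].to_csv(path, index=False)


def read_census_table(path) -> pd.DataFrame:
    """Read and validate a census table written by :func:`write_census_table`.

    Rejects malformed rows: non-census days (not multiples of 4 in
    [0, 148]) and negative counts, naming the offending row numbers.
    """
    table = pd.read_csv(path, comment="#")
    missing = [c for c in CENSUS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"census table is missing columns {missing}")
    table["harvest"] = table["harvest"].astype(bool)
    bad_day = table.index[
        (table["day"] % 4 != 0) | (table["day"] < 0) | (table["day"] > 148)
    ].tolist()
    if bad_day:
        raise ValueError(f"rows {bad_day}: day is not a census day (0, 4, ..., 148)")
    counts = table[["eggs", "juveniles", "adults"]]
    bad_count = table.index[(counts < 0).any(axis=1)].tolist()
    if bad_count:
        raise ValueError(f"rows {bad_count}: negative counts")
    return table


def drop_tube(
    table: pd.DataFrame,
    colour: str,
    harvest: bool,
    tube: int,
    from_day: int = 0,
) -> pd.DataFrame:
    """Remove one tube's censuses from *from_day* onward.

    Emulates the experiment's dropped tube, producing unbalanced strata
    for the bootstrap machinery.
    """
    mask = (
        (table["colour"] == colour)
        & (table["harvest"] == harvest)
        & (table["tube"] == tube)
        & (table["day"] >= from_day)
    )
    return table[~mask].reset_index(drop=True)
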