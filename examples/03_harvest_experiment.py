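"""Replay the 148-day harvesting experiment in silico.

Twenty founder adults acclimate for 31 days on the control ration, then
the population follows a coloured food series (here: low ration maps to
E(Y) = 0.25, high to 0.45).  Every 4th day a census splits the female
size distribution into eggs, juveniles and adults; every 8th day the
harvested treatment removes 50% of adults longer than 1.0235 times the
current mean adult length.  The stochastic growth rate log lambda_s is
the mean daily log growth ratio over the experimental window.
"""

import numpy as np

from debipm import DEBParams, HarvestRule, default_grid, run_experiment_simulation
from debipm.analysis import experiment_food_series
from debipm.population import NO_HARVEST

params = DEBParams()
grid = default_grid(params)
foods = experiment_food_series(seed=0)

def mean_log(series):
    """Mean log count over censuses where the stage is present.

    On low-ration days the plastic maturation length drops below every
    mesh size, so the whole population counts as adult and the egg and
    juvenile classes are empty; those censuses are excluded.
    """
    positive = series[series > 0]
    return np.log(positive).mean() if len(positive) else float("nan")


print("colour   harvest   log lambda_s   mean log counts (eggs / juv / adults)")
for colour, food in foods.items():
    for rule, label in ((NO_HARVEST, "no "), (HarvestRule(), "yes")):
        res = run_experiment_simulation(
            food, params, grid, rule=rule, ey_low=0.25, ey_high=0.45
        )
        f = res.census_frame()
        logs = [mean_log(f[stage]) for stage in ("eggs", "juveniles", "adults")]
        print(
            f"{colour:>6}     {label}      {res.log_lambda_s:+.4f}       "
            f"{logs[0]:.2f} / {logs[1]:.2f} / {logs[2]:.2f}"
        )

print(
    "\nHarvesting always lowers log lambda_s slightly: removing the largest"
    "\nadults trims the most fecund size classes, but the rest of the"
    "\npopulation partly compensates within a few days."
)
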