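"""Generate a mock observed study and run the prediction-vs-observation
comparison end to end.

The generator simulates one treatment (white noise, unharvested), doubles
female counts to mixed-sex observed conventions, adds 20% multiplicative
lognormal observation noise per replicate tube, and rounds to integer
counts.  Reading the table back, halving to female counts, and
bootstrapping the mean log adult count (1,000 stratified BCa resamples,
strata = tubes) yields a confidence interval that should cover the
noise-free prediction.
"""

import numpy as np

from debipm import DEBParams, bootstrap_bca, default_grid, overlap_test
from debipm.synthetic import (
    SyntheticStudyConfig,
    generate_study,
    simulate_truth,
    to_female_counts,
)

params = DEBParams()
grid = default_grid(params)
config = SyntheticStudyConfig(colours=("white",), harvests=(False,), noise_sd=0.2, seed=7)

truth = simulate_truth(config, params, grid)
predicted = float(np.log(truth[("white", False)].census_frame()["adults"]).mean())

table = generate_study(config, params, grid, truth=truth)
print(table.head(6).to_string(index=False))
print(f"... {len(table)} rows: 3 tubes x 37 censuses")

females = to_female_counts(table)
ci = bootstrap_bca(
    np.log(females["adults"].to_numpy()), females["tube"].to_numpy(), seed=7
)
verdict = "consistent" if overlap_test(ci, predicted) else "inconsistent"
print(
    f"\nobserved mean log adults: {ci.estimate:.3f} "
    f"(95% BCa CI {ci.lower:.3f} to {ci.upper:.3f})"
    f"\npredicted (noise-free) value: {predicted:.3f} -> {verdict}"
)
print(
    "\n'Consistent' means the deterministic prediction lies inside the"
    "\nbootstrap interval of the noisy observations, i.e. the comparison"
    "\npipeline recovers the generating model."
)
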