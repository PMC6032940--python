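"""Construct the experiment's coloured food regimes.

A white 37-step series randomly orders 20 good (8 yeast rods/day) and 17
bad (2 rods/day) 4-day blocks.  Spectral mimicry then rearranges the same
values to follow autocorrelated surrogates, and pairwise-swap hill
climbing pushes the lag-1 autocorrelation to its attainable extremes: a
blue series (rapid alternation, strongly negative autocorrelation) and a
red series (long runs of good and bad spells, strongly positive).
All three series share the same mean, variance, minimum and maximum —
only the temporal arrangement differs.
"""

from debipm import lag1_autocorrelation, make_white_series, optimise_autocorrelation

white = make_white_series(seed=0)
blue, rho_blue = optimise_autocorrelation(white, "minimize", seed=0)
red, rho_red = optimise_autocorrelation(white, "maximize", seed=0)

for series in (blue, white, red):
    v = series.values
    rho = lag1_autocorrelation(v)
    print(
        f"{series.colour_label:>5}: rho_1 = {rho:+.3f}   "
        f"mean = {v.mean():.2f}  var = {v.var(ddof=1):.2f}   "
        f"rods: {' '.join(str(r) for r in series.rods_per_step)}"
    )

print(
    "\nrho_1 is the lag-1 autocorrelation of the 37-step series; the blue"
    "\nand red values are the extremes reachable by permutation, bracketing"
    "\nany realisable noise-colour treatment for this value distribution."
)
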