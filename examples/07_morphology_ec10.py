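"""Morphology EC10 from deep-learning tile 'altered' probabilities.

Simulates per-tile probabilities from a variable-dispersion beta model
whose mean rises with log10 concentration, fits the double-index beta
regression, and inverts the fitted mean for the EC10 — the concentration at
10% of the fitted response range — with a delta-method confidence interval.
"""

import hepapod as hp
from hepapod import morpho

design = hp.make_design(1, 500.0, 9)
tiles = hp.simulate_tile_scores(
    design, beta_mean_params=(-2.0, 0.9), beta_precision_params=(4.5, 0.2),
    n_tiles_per_well=16, seed=5,
)
screen = hp.screen_altered(tiles)
print("substances with any altered tile:",
      int(screen["active"].sum()), "of", len(screen))

fit = morpho.fit_beta(tiles[tiles["run"] == "R1"])
b0, b1 = fit.mean_coef
g0, g1 = fit.precision_coef
print(f"mean model   logit(mu)  = {b0:+.2f} {b1:+.2f} * log10(conc)")
print(f"precision    log(phi)   = {g0:+.2f} {g1:+.2f} * log10(conc)")

res = morpho.ec10(fit, level=0.95)
print(f"\nEC10 = {res.ec10:.2f} uM  (95% CI {res.ci_lower:.2f} - "
      f"{res.ci_upper:.2f})")
print("The CI is built on the log10-concentration scale and exponentiated.")
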