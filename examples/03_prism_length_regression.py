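"""Robust through-origin regression of secretion days on prism length.

The slope (days/µm) is the reciprocal of a length-weighted mean daily
secretion rate; with it, a crown chronology can be estimated in teeth
whose daily cross-striations are not legible. The bisquare M-estimator
shrugs off gross outliers that visibly bias ordinary least squares.
"""

import numpy as np

from odontochron import fit_origin_robust, ols_origin, predict_days
from odontochron.regression import simulate_length_day_pairs

pairs = simulate_length_day_pairs(500, mean_dsr=3.17, sd_dsr=0.26, seed=1)
fit = fit_origin_robust(pairs)
print(f"robust slope: {fit.slope:.4f} days/µm  (1/3.17 = {1 / 3.17:.4f})")
print(f"adjusted R² (uncentered, {fit.adjusted_r2_note}): {fit.adjusted_r2:.3f}")
print(f"a 1000 µm prism ≙ {predict_days(1000.0, fit):.0f} days of matrix secretion")

# contaminate a perfect line with 20% gross outliers
rng = np.random.default_rng(3)
x = rng.uniform(50, 2000, 100)
y = x / 3.17
y[rng.choice(100, 20, replace=False)] += rng.uniform(100, 300, 20)
robust = fit_origin_robust((x, y)).slope
ols = ols_origin((x, y))
print(f"\nwith 20% outliers: robust slope {robust:.4f}, OLS slope {ols:.4f}")
print("The robust slope stays on the true line; OLS is dragged upward.")
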