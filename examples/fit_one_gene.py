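"""Fit the skew-normal model to one gene's CLR values and test its fit.

Shows the centered parameter estimates (mean, SD, skewness) with their
standard errors, and the Kolmogorov-Smirnov goodness of fit of the model.
"""

import numpy as np

from clrdv import (
    SimDesign,
    clr_transform,
    fit_sn_cp,
    ks_stat,
    simulate_two_groups,
    synth_nb2_params,
)

params = synth_nb2_params(100, seed=7)
counts, _, groups = simulate_two_groups(
    params, SimDesign(G=100, prop_dv=0.0, n_per_group=250, seed=7)
)
clr = clr_transform(counts)

values = clr.iloc[0].to_numpy()
fit = fit_sn_cp(values)
print(f"gene {clr.index[0]}, n = {values.size}, method = {fit.method}")
print(f"mu    = {fit.cp.mu:.3f}  (s.e. {fit.se[0]:.3f})   CLR mean")
print(f"sigma = {fit.cp.sigma:.3f}  (s.e. {fit.se[1]:.3f})   CLR standard deviation")
print(f"gamma = {fit.cp.gamma:.3f}  (s.e. {fit.se[2]:.3f})   skewness, |gamma| < 0.9953")

d, p = ks_stat(values, fit.cp)
print(f"KS goodness of fit: D = {d:.4f}, p = {p:.3f} "
      f"({'adequate' if p > 0.05 else 'poor'} fit at the 0.05 threshold)")
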