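"""Recover the null-distribution parameters from model-faithful data.

Draws signals from the generative variance model (normal signals whose
precision is chi-square around a known mean-variance curve) with 5%
hypervariable contamination, then compares three moment-matching variants.
"""

from hypervar import estimation, mvc, synthesis

cfg = synthesis.SimulationConfig(seed=42)  # n=20000, m=10, d0=5, gamma=1.2
x, truth = synthesis.simulate_normalized(cfg)

curve = mvc.MeanVarianceCurve.from_function(cfg.mvc, *cfg.mu_range)
table = mvc.scaled_variances(mvc.mean_variance(x), curve)

plain = estimation.fit_model(table, curve, fraction=1.0, p_l=0, p_u=0)
lower10 = estimation.fit_model(table, curve, fraction=0.1, p_l=0, p_u=0)
full = estimation.fit_model(table, curve)  # lower 10% + winsorization

print(f"true parameters:            d0 = {cfg.d0_true}, gamma = {cfg.gamma_true}")
print(f"plain moment matching:      d0 = {plain.d0:.2f}, gamma = {plain.gamma:.3f}")
print(f"lowest-10% selection:       d0 = {lower10.d0:.2f}, gamma = {lower10.gamma:.3f}")
print(f"selection + winsorization:  d0 = {full.d0:.2f}, gamma = {full.gamma:.3f}")
# Contaminating HVRs inflate the spread of log scaled variances, which the
# plain estimator reads as a smaller d0 (heavier null tail, weaker tests).
# Selecting low-intensity regions, where HVRs are scarce, removes most of
# that bias; winsorization tames the few that remain.
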