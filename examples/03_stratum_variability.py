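"""Compare global signal variability between two region strata.

Distal regulatory regions typically vary more across individuals than
promoter-proximal ones.  With d0 pinned to +infinity and no low-intensity
selection, the gamma estimate of each stratum is the factor by which a
shared mean-variance curve must be scaled to reach that stratum's
variances, so the gamma ratio measures relative global variability.
"""

import math

import pandas as pd

from hypervar import estimation, mvc, synthesis

shared = dict(n_regions=8000, d0_true=math.inf, hvr_fraction=0.0)
proximal_cfg = synthesis.SimulationConfig(gamma_true=1.0, seed=10, **shared)
distal_cfg = synthesis.SimulationConfig(gamma_true=2.0, seed=11, **shared)

xp, _ = synthesis.simulate_normalized(proximal_cfg)
xd, _ = synthesis.simulate_normalized(distal_cfg)
xd.index = [f"chr2:{1000 * i}-{1000 * (i + 1)}" for i in range(len(xd))]

# normalization and curve fitting run on both strata together
x = pd.concat([xp, xd])
table = mvc.mean_variance(x)
curve = mvc.fit_mvc(table)
table = mvc.scaled_variances(table, curve)


def stratum_table(idx):
    return mvc.MeanVarianceTable(
        mu_hat=table.mu_hat.loc[idx], t_hat=table.t_hat.loc[idx],
        m=table.m, scaled=table.scaled.loc[idx], z=table.z.loc[idx],
    )


g_prox = estimation.estimate_gamma_fixed_d0(stratum_table(xp.index), curve)
g_dist = estimation.estimate_gamma_fixed_d0(stratum_table(xd.index), curve)
print(f"gamma (proximal stratum): {g_prox:.3f}")
print(f"gamma (distal stratum):   {g_dist:.3f}")
print(f"distal / proximal ratio:  {g_dist / g_prox:.3f}")
# The simulation doubled the distal variances around the shared curve, and
# the fixed-d0 comparison recovers a ratio close to 2.
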