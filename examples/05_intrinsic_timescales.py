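"""Recover a planted hierarchy of intrinsic neural timescales.

Three regions are simulated with AR(1) coefficients 0.2, 0.5 and 0.8. The
intrinsic timescale — TR times the sum of the sample ACF up to the lag before
it first turns non-positive — should be ordered accordingly, and for
phi = 0.5 it should sit near the geometric-sum value 1.5 * 1/(1-0.5) = 3.0 s.
"""

import warnings

import numpy as np

from bindnet import SimulationConfig, acf_estimate, compare_timescales, intrinsic_timescale, simulate_panel
from bindnet.timescale import timescale_table

warnings.filterwarnings("ignore")

config = SimulationConfig(
    n_subjects=20, n_regions=3, n_frames=600, base_r=0.0, delta_r=0.0,
    planted_edges=(), phi=np.array([0.2, 0.5, 0.8]), seed=2,
)

panels = {(s, "binding"): simulate_panel(config, s, "binding") for s in range(20)}
table = timescale_table(panels, max_lag=100)

means = table.groupby("region")["timescale_seconds"].mean()
for region, phi in zip(config.region_labels, config.phi):
    print(f"{region} (phi={phi}): mean timescale {means[region]:.2f} s")

pairs = compare_timescales(table)
print("\npairwise comparisons (paired t, BH-FDR):")
print(pairs[["region_a", "region_b", "t", "p_adjusted", "significant"]]
      .round(4).to_string(index=False))
# Shorter timescale = more transient activity; the phi = 0.2 region should be
# significantly shorter than both others.
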