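"""Compute the 20-feature fingerprint of single trajectories.

Simulates one Brownian and one subdiffusive (fractional Brownian)
trajectory and prints their fingerprints side by side.  The scaling
exponent alpha, fractal dimension and trappedness respond to the motion
type; the rheological features translate the MSD into medium properties.
"""

import pandas as pd

from diffprint import ParticleContext, fingerprint
from diffprint.simulate import SimulationConfig, simulate

ctx = ParticleContext.from_diameter_nm(1000)  # 1 um tracer at 37 degC

brownian, _ = simulate(SimulationConfig(model="brownian", D=0.2,
                                        loc_noise_sigma=0.02), seed=1)
subdiff, _ = simulate(SimulationConfig(model="fbm", D=0.2, hurst_H=0.25,
                                       loc_noise_sigma=0.02), seed=1)

table = pd.DataFrame({
    "brownian": fingerprint(brownian[0], ctx),
    "subdiffusive (H=0.25)": fingerprint(subdiff[0], ctx),
})
print(table.round(4))
ratios = (table.loc["mean_Gprime"] / table.loc["mean_Gdoubleprime"]).round(2)
print(f"\nG'/G'' ratios: {ratios.to_dict()}")
print("alpha ~ 1 vs ~ 0.5 separates the motion types; the subdiffusive walk "
      "has higher trappedness and fractal dimension, and its larger G'/G'' "
      "ratio reflects a more elastic apparent environment.")
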