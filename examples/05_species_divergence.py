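"""Two species diverging with heterogeneous regional mutation rates.

An ancestor is evolved to stationarity, duplicated (speciation), and the
two descendants evolve with fresh region-wise Exponential(1) rates.  For
small divergence the comparative MLD tail is exponential (stick
breaking); for deep divergence the rate heterogeneity produces a -4
power law carried by the conserved (slow) regions.
"""

import numpy as np

from mldkit import evolve, fitting, mems
from mldkit.evolve import SimConfig

rng = np.random.default_rng(11)

# shallow divergence: many long orthologous matches, exponential-type tail
cfg = SimConfig(L=100_000, mu=1.0, lam=1e-3, K=1000, M=1000, t1=0.01)
pair = evolve.simulate_divergence_pair(cfg, rng)
ms = mems.find_mems(evolve.codes_to_sequence(pair.codes_a),
                    evolve.codes_to_sequence(pair.codes_b), minlen=20)
lens = sorted(m.length for m in ms)
print(f"t1=0.01: {len(ms)} matches >= 20 bp, median {lens[len(lens)//2]}, "
      f"longest {lens[-1]}")

# deep divergence: fewer matches, power-law tail with slope near -4
cfg = SimConfig(L=100_000, mu=1.0, lam=1e-3, K=1000, M=1000, t1=2.0)
pooled = evolve.comparative_mld_ensemble(cfg, n_reps=60, rng=rng)
fit = fitting.fit_tail_exponent(mems.log_bin(pooled, 1.25, start=20), r_lo=30.0)
print(f"t1=2 (60 pairs): alpha = {fit.exponent:.2f} +- {fit.stderr:.2f}, "
      f"{fit.n_matches_in_tail} tail matches")
print("The long matches all come from region pairs that drew small rates"
      " in both species - the simulated analogue of conserved elements.")
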