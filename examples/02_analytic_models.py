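"""Analytic MLD models and the exponent rule alpha = -(3 + beta).

Evaluates the stick-breaking kernel, the pair-density models, and shows
how the small-tau behaviour of N(tau) sets the power-law tail of the MLD
via numeric integration.
"""

import numpy as np

from mldkit import models
from mldkit.fitting import loglog_slope
from mldkit.models import EvolParams, PairDensity

# chance matches in a 1 Gbp random genome: essentially none beyond 30 bp
rs = np.arange(31, 2000)
print(f"expected iid matches > 30 bp at L=1e9: "
      f"{models.iid_mld(rs, L=1e9, p=0.25).sum():.3f}")

# a pair of 1 Gbp orthologs at 25% divergence: one surviving 72-bp match
print(f"stick-breaking m(72 bp, tau=0.25, K=1e9) = "
      f"{models.stick_mld(72, tau=0.25, K=1e9):.2f}")

# longest match expected from neutral duplication dynamics
print(f"rmax(A=1,   L=1e9) = {models.rmax(1.0, 1e9, 1e4):.0f} bp")
print(f"rmax(A=0.1, L=1e9) = {models.rmax(0.1, 1e9, 1e4):.0f} bp")

# the exponent rule: N(tau) ~ tau^beta  =>  m(r) ~ r^-(3+beta)
r_grid = np.geomspace(100, 10_000, 13)
for beta in (0, 1, 2):
    dens = PairDensity.from_function(lambda t, b=beta: t**b, (0.0, 1.0))
    slope, _ = loglog_slope(r_grid, models.mld_from_density(r_grid, dens, K=1e6))
    print(f"beta={beta}: fitted slope {slope:+.3f} "
          f"(rule says {models.exponent_from_beta(beta):+.0f})")

# closed-form tails vs the integral, for the Yule family density
ep = EvolParams(mu=1.0, lam=1e-3, K=1000.0, T=3.0)
num = models.mld_from_density(100.0, models.yule_density(ep), K=ep.K)
print(f"Yule tail at r=100: closed form {models.yule_mld_tail(100, ep):.4f}, "
      f"numeric integral {num:.4f}")
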