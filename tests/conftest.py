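import numpy as np
import pytest

from mldkit import evolve
from mldkit.evolve import SimConfig


@pytest.fixture
def rng():
    """A fresh, fixed-seed generator per test."""
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# Shared simulation ensembles (expensive; computed once per session).
# Scales are chosen so that each pooled tail holds enough matches for a
# stable exponent estimate while the whole suite stays desk-sized.

@pytest.fixture(scope="session")
def randomdup_ensemble():
    """Pooled stationary self-alignment MLD: 80 genomes of 1e5 bp,
    mu=1, lambda=1e-3, K=1000, burn-in 5 substitutions per site."""
    rng = np.random.default_rng(1001)
    cfg = SimConfig(L=100_000, mu=1.0, lam=1e-3, K=1000)
    return evolve.self_mld_ensemble(cfg, 80, rng)


@pytest.fixture(scope="session")
def retro_ensemble():
    """Pooled copy-family MLD: 100 retro families, source K=1000 bp
    duplicating at lam*K=50 per unit time for T=2, copies at mu=1,
    source at a*mu with a=0.1."""
    rng = np.random.default_rng(1002)
    cfg = SimConfig(L=100_000, mu=1.0, lam=0.05, K=1000, mode="retro", a=0.1)
    return evolve.retro_family_mld(cfg, duration=2.0, n_reps=100, rng=rng)


@pytest.fixture(scope="session")
def diverge_ensemble():
    """Pooled comparative MLD: 400 pairs of 1e5 bp diverged for t1=2 from
    stationary ancestors under region-wise Exponential(1) rates, M=1000."""
    rng = np.random.default_rng(1003)
    cfg = SimConfig(L=100_000, mu=1.0, lam=1e-3, K=1000, M=1000, t1=2.0)
    return evolve.comparative_mld_ensemble(cfg, 400, rng)
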