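"""Analytic MLD models: closed forms, pair densities and their oracles."""

from fractions import Fraction

import numpy as np
import pytest
from scipy import integrate

from mldkit import models
from mldkit.fitting import loglog_slope
from mldkit.models import EvolParams, PairDensity


# ---------------------------------------------------------------------------
# iid baseline

def test_iid_cumulative_beyond_30_below_one():
    rs = np.arange(31, 2000)
    for convention in ("half", "full"):
        total = models.iid_mld(rs, L=1e9, p=0.25, convention=convention).sum()
        assert total < 1.0


def test_iid_closed_form_matches_exact_arithmetic():
    # exact rational evaluation of L^2 (1/2)(1-p)^2 p^r
    L, r = 10**9, 27
    exact = Fraction(L) ** 2 * Fraction(1, 2) * Fraction(3, 4) ** 2 * Fraction(1, 4) ** r
    got = models.iid_mld(r, L=1e9, p=0.25, convention="half")
    assert got == pytest.approx(float(exact), rel=1e-12)
    assert models.iid_mld(r, L=1e9, p=0.25, convention="full") == pytest.approx(
        2 * float(exact), rel=1e-12
    )


def test_iid_vanishes_for_small_p():
    assert models.iid_mld(5, L=1e9, p=1e-12) == pytest.approx(0.0, abs=1e-30)


# ---------------------------------------------------------------------------
# stick breaking

def test_stick_expected_single_72bp_match_at_quarter_divergence():
    # tau = 0.25, K = 1 Gbp: one expected match of 72 bp
    assert round(models.stick_mld(72, tau=0.25, K=1e9)) == 1


def test_stick_zero_divergence_and_domain():
    assert models.stick_mld(100, tau=0.0, K=1e4) == 0.0
    with pytest.raises(ValueError):
        models.stick_mld(10, tau=0.1, K=10)


def test_stick_matches_fragmentation_monte_carlo(rng):
    tau, K, n_sticks = 0.05, 1e4, 6000
    hist = np.zeros(220)
    for _ in range(n_sticks):
        breaks = np.sort(rng.uniform(0, K, rng.poisson(K * tau)))
        frags = np.diff(np.concatenate(([0.0], breaks, [K])))
        h, _ = np.histogram(frags, bins=220, range=(0, 220))
        hist += h
    zs = []
    for r in range(20, 201):
        expected = n_sticks * integrate.quad(
            lambda x: models.stick_mld(x, tau, K), r, r + 1
        )[0]
        zs.append((hist[r] - expected) / np.sqrt(expected))
    zs = np.abs(zs)
    # fragment counts within a stick are correlated, so allow mild
    # overdispersion relative to the Poisson scale
    assert zs.max() < 5.0
    assert (zs > 3.0).mean() < 0.05
    assert zs.mean() < 1.5


# ---------------------------------------------------------------------------
# pair densities

def test_yule_density_support_and_origin():
    ep = EvolParams(mu=1.0, lam=1e-3, K=1000.0, T=5.0)
    assert models.yule_pair_density(10.0 + 1e-9, ep) == 0.0
    assert models.yule_pair_density(-0.1, ep) == 0.0
    lamK = ep.lam * ep.K
    assert models.yule_pair_density(0.0, ep) == pytest.approx(
        lamK / (2 * ep.mu) * np.exp(lamK * ep.T)
    )


def test_yule_density_matches_tree_monte_carlo(rng):
    from mldkit.trees import simulate_yule_tree

    ep = EvolParams(mu=1.0, lam=1e-3, K=1000.0, T=5.0)
    edges = np.linspace(0, 10, 21)
    per_tree = []
    for _ in range(1500):
        s = simulate_yule_tree(1.0, 1.0, 5.0, rng)
        h, _ = np.histogram(s.values, bins=edges, weights=s.weights)
        per_tree.append(h)
    per_tree = np.asarray(per_tree, dtype=float)
    widths = np.diff(edges)
    mean = per_tree.mean(axis=0) / widths
    sem = per_tree.std(axis=0, ddof=1) / np.sqrt(len(per_tree)) / widths
    centers = 0.5 * (edges[:-1] + edges[1:])
    theory = models.yule_pair_density(centers, ep)
    z = np.abs((mean - theory) / sem)
    assert z.max() < 4.0 and z.mean() < 2.0


def test_retro_density_shape_properties():
    ep = EvolParams(mu=1.0, lam=2e-3, K=500.0, T=1.0, a=0.1)
    assert models.retro_pair_density(0.0, ep) == 0.0
    taus = np.linspace(0, 2, 4001)
    dens = models.retro_pair_density(taus, ep)
    assert taus[np.argmax(dens)] == pytest.approx((1 + ep.a) * ep.mu * ep.T, abs=2e-3)
    assert dens[-1] == pytest.approx(0.0, abs=1e-12)
    # integrates to the expected number of pseudogene pairs (lam K T)^2/2
    total, _ = integrate.quad(lambda t: models.retro_pair_density(t, ep), 0, 2, limit=200)
    assert total == pytest.approx((ep.lam * ep.K * ep.T) ** 2 / 2, rel=1e-6)
    with pytest.raises(ValueError):
        EvolParams(a=1.0)


def test_retro_density_matches_pairwise_time_sampling(rng):
    mu, a, T = 1.0, 0.1, 1.0
    n = 500_000
    t1 = rng.uniform(0, T, n)
    t2 = rng.uniform(0, T, n)
    tau = mu * (2 * T - t1 - t2) + a * mu * np.abs(t1 - t2)
    h, edges = np.histogram(tau, bins=40, range=(0, 2 * mu * T))

    def cdf(s):  # exact integral of the triangular shape
        s = np.clip(s / (mu * T), 0, 2)
        return np.where(s <= 1 + a, s**2 / (2 * (1 + a)), 1 - (2 - s) ** 2 / (2 * (1 - a)))

    expected = n * np.diff(cdf(edges))
    z = np.abs(h - expected) / np.sqrt(expected)
    # familywise bounds for 40 Poisson bins
    assert z.max() < 4.2
    assert (z > 3.0).sum() <= 2
    assert z.mean() < 1.5


# ---------------------------------------------------------------------------
# convolution

def test_convolution_vanishes_at_origin():
    na = PairDensity.from_function(lambda t: np.ones_like(t), (0, 1))
    nb = PairDensity.from_function(lambda t: np.ones_like(t), (0, 1))
    conv = models.convolve_pair_density(na, nb)
    assert conv(0.0) == 0.0


def test_convolution_of_uniforms_is_triangular():
    na = PairDensity.from_function(lambda t: np.ones_like(t), (0, 1))
    conv = models.convolve_pair_density(na, na)
    grid = np.linspace(0, 2, 201)
    vals = conv(grid)
    assert grid[np.argmax(vals)] == pytest.approx(1.0, abs=0.02)
    assert vals[100] == pytest.approx(1.0, abs=0.02)  # peak height of the triangle
    assert conv(1.5) == pytest.approx(0.5, abs=0.02)


def test_convolution_of_exponentials_matches_closed_form():
    na = PairDensity.from_function(lambda t: np.exp(-t), (0, 40))
    nb = PairDensity.from_function(lambda t: 2 * np.exp(-2 * t), (0, 40))
    conv = models.convolve_pair_density(na, nb, n_grid=8192)
    for tau in (0.5, 1.0, 2.0, 4.0):
        closed = 2 * (np.exp(-tau) - np.exp(-2 * tau))
        assert conv(tau) == pytest.approx(closed, rel=0.02)


# ---------------------------------------------------------------------------
# the MLD integral and its exponent regimes

@pytest.mark.parametrize(
    "beta,slope_tol",
    [(0, 0.02), (1, 0.02), (2, 0.05)],
)
def test_mld_integral_exponent_regimes(beta, slope_tol):
    # N(tau) ~ tau^beta near zero gives m(r) ~ r^-(3+beta)
    density = PairDensity.from_function(lambda t, b=beta: t**b, (0.0, 1.0))
    rs = np.geomspace(100, 10_000, 13)
    m = models.mld_from_density(rs, density, K=1e6)
    slope, _ = loglog_slope(rs, m)
    assert slope == pytest.approx(models.exponent_from_beta(beta), abs=slope_tol)


def test_yule_tail_closed_form():
    ep = EvolParams(mu=1.0, lam=1e-3, K=1000.0, T=3.0)
    assert models.yule_mld_tail(200, ep) / models.yule_mld_tail(100, ep) == pytest.approx(1 / 8)
    exact = (
        Fraction(1, 1000) * Fraction(1000) ** 2 / Fraction(100) ** 3
    )  # lam K^2 / (mu r^3); e^(lamKT) applied below
    assert models.yule_mld_tail(100, ep) == pytest.approx(
        float(exact) * np.exp(3.0), rel=1e-12
    )
    # numeric-integral oracle inside the validity range lamK/(2mu) << r < K
    rs = np.array([50.0, 100.0, 200.0, 300.0])
    numeric = models.mld_from_density(rs, models.yule_density(ep), K=ep.K)
    assert np.all(np.abs(numeric / models.yule_mld_tail(rs, ep) - 1) < 0.05)


def test_random_dup_tail_closed_form():
    ep = EvolParams(mu=1.0, lam=1e-3, K=1000.0, L=1e9)
    assert models.random_dup_mld_tail(1000, ep) == pytest.approx(1.0)
    ep2 = EvolParams(mu=1.0, lam=1e-3, K=1000.0, L=2e9)
    assert models.random_dup_mld_tail(1000, ep2) == pytest.approx(2.0)
    # constant pair density N0 = A L / (2K) reproduces A L / r^3 exactly
    n0 = ep.A * ep.L / (2 * ep.K)
    density = PairDensity.from_function(lambda t: np.full_like(t, n0), (0.0, 2.0))
    rs = np.array([50.0, 100.0, 300.0])
    numeric = models.mld_from_density(rs, density, K=ep.K)
    assert np.all(np.abs(numeric / models.random_dup_mld_tail(rs, ep) - 1) < 0.05)


def test_retro_tail_closed_form():
    ep = EvolParams(mu=1.0, lam=1e-3, K=1000.0, T=50.0, a=0.1)
    assert models.retro_mld_tail(60, ep) / models.retro_mld_tail(30, ep) == pytest.approx(
        1 / 16
    )
    ep_a0 = EvolParams(mu=1.0, lam=1e-3, K=1000.0, T=50.0, a=0.0)
    assert models.retro_mld_tail(50, ep) / models.retro_mld_tail(50, ep_a0) == pytest.approx(
        1 / 1.1
    )
    # numeric oracle over the tail range r << K (long T so r T mu >> 1)
    rs = np.array([30.0, 50.0, 80.0])
    numeric = models.mld_from_density(rs, models.retro_density(ep), K=ep.K)
    assert np.all(np.abs(numeric / models.retro_mld_tail(rs, ep) - 1) < 0.05)


def test_comparative_tail_closed_form():
    K, slope0 = 1000.0, 3.5
    assert models.comparative_mld_tail(3 * K, slope0, K) == 0.0
    rs = np.geomspace(5, 50, 8)
    slope, _ = loglog_slope(rs, models.comparative_mld_tail(rs, slope0, K))
    assert slope == pytest.approx(-4.0, abs=0.05)
    density = PairDensity.from_function(lambda t: slope0 * t, (0.0, 5.0))
    numeric = models.mld_from_density(rs, density, K=K)
    assert np.all(np.abs(numeric / models.comparative_mld_tail(rs, slope0, K) - 1) < 0.05)


# ---------------------------------------------------------------------------
# rmax and exponents

def test_rmax_worked_values():
    assert models.rmax(1.0, 1e9, 1e4) == pytest.approx(1000.0)
    assert models.rmax(0.1, 1e9, 1e4) == pytest.approx(464.16, abs=0.01)
    assert models.rmax(1.0, 1e9, 500.0) == 500.0


def test_rmax_monotone_and_capped():
    grid = np.geomspace(1e-3, 10, 8)
    vals = [models.rmax(a, 1e9, 2000.0) for a in grid]
    assert all(x <= y for x, y in zip(vals, vals[1:]))
    assert all(v <= 2000.0 for v in vals)
    valsL = [models.rmax(0.5, L, 2000.0) for L in np.geomspace(1e6, 1e12, 7)]
    assert all(x <= y for x, y in zip(valsL, valsL[1:]))


@pytest.mark.parametrize("beta,alpha", [(0, -3.0), (1, -4.0), (2, -5.0)])
def test_exponent_from_beta(beta, alpha):
    assert models.exponent_from_beta(beta) == alpha
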