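"""Analytic match length distribution (MLD) models.

The central object is the pair density N(tau): the number of pairs of
duplicated (or orthologous) sequence segments separated by a dimensionless
evolutionary distance tau (expected substitutions per site along the path
connecting them).  Mutations fragment an initially identical pair of
segments of length K into maximal exact matches; for a single pair at
distance tau the expected number of matches of length r is the
stick-breaking kernel

    m(r, tau) = [2 tau + tau^2 (K - r)] exp(-tau r),

and the MLD of a whole genome is the integral of this kernel against
N(tau).  The small-tau behaviour of N controls the tail exponent of the
MLD: N(tau) ~ tau^beta gives m(r) ~ r^-(3+beta), hence the -3 regime for
ongoing random/segmental duplication (N(0) > 0), -4 for retroduplicated
pseudogene families and for comparative alignments of diverged species
(N(0) = 0, N'(0) > 0), and -5 when the first derivative vanishes too.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import integrate

__all__ = [
    "EvolParams",
    "PairDensity",
    "iid_mld",
    "stick_mld",
    "yule_pair_density",
    "retro_pair_density",
    "retro_pair_shape",
    "convolve_pair_density",
    "mld_from_density",
    "yule_mld_tail",
    "random_dup_mld_tail",
    "retro_mld_tail",
    "comparative_mld_tail",
    "rmax",
    "exponent_from_beta",
]


@dataclass
class EvolParams:
    """Rates and lengths shared by the models and the simulators.

    mu   -- point mutation rate per bp per unit time (an effective rate:
            short indels act on exact matches just like substitutions)
    lam  -- duplication rate per bp per unit time
    K    -- length of a duplicated segment (bp)
    T    -- elapsed time since the process started
    a    -- mutation-rate ratio mu_source / mu of a retro source gene, in [0, 1)
    L    -- genome length (bp)
    p    -- probability that two bases match by chance (1/4 for uniform use)
    M    -- length of a constant-mutation-rate region (bp)
    t1   -- divergence time after a speciation event
    """

    mu: float = 1.0
    lam: float = 1e-3
    K: float = 1000.0
    T: float = 1.0
    a: float = 0.0
    L: float = 1e5
    p: float = 0.25
    M: float = 1000.0
    t1: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.a < 1):
            raise ValueError("rate ratio a must lie in [0, 1)")
        if not (0 < self.p < 1):
            raise ValueError("p must lie in (0, 1)")
        for name in ("mu", "lam", "K", "T", "L", "M"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def A(self) -> float:
        """Dimensionless duplication prefactor lambda*K/mu."""
        return self.lam * self.K / self.mu


@dataclass
class PairDensity:
    """A density of segment pairs over evolutionary distance tau.

    ``fn`` evaluates the density inside ``support``; the callable wrapper
    clips it to zero outside.  ``total`` (when known) is the integral, i.e.
    the number of pairs the density describes.
    """

    fn: Callable[[np.ndarray], np.ndarray]
    support: tuple[float, float]
    form: str = "user-function"
    total: float | None = None

    def __call__(self, tau):
        arr = np.atleast_1d(np.asarray(tau, dtype=float))
        lo, hi = self.support
        inside = (arr >= lo) & (arr <= hi)
        out = np.zeros_like(arr, dtype=float)
        if np.any(inside):
            out[inside] = np.asarray(self.fn(arr[inside]), dtype=float)
        return out if np.asarray(tau).ndim else float(out[0])

    @classmethod
    def from_function(cls, fn, support, form="user-function", total=None):
        return cls(fn=fn, support=tuple(support), form=form, total=total)

    @classmethod
    def from_histogram(cls, edges: np.ndarray, weights: np.ndarray) -> "PairDensity":
        """Empirical step density; integrates to the summed weights."""
        edges = np.asarray(edges, dtype=float)
        weights = np.asarray(weights, dtype=float)
        dens = weights / np.diff(edges)

        def step(tau, edges=edges, dens=dens):
            idx = np.clip(np.searchsorted(edges, tau, side="right") - 1, 0, dens.size - 1)
            return dens[idx]

        return cls(
            fn=step,
            support=(float(edges[0]), float(edges[-1])),
            form="empirical-histogram",
            total=float(weights.sum()),
        )


def iid_mld(r, L: float, p: float = 0.25, convention: str = "half"):
    """Expected chance-match count of length r between iid sequences.

    ``convention='half'`` counts unordered segment pairs, L^2/2 (1-p)^2 p^r
    (the natural convention for a self-alignment); ``'full'`` drops the
    1/2 (one count per ordered A-B position pair, the convention realised
    by a comparative alignment of two distinct sequences).
    """
    r = np.asarray(r, dtype=float)
    base = L * L * (1 - p) ** 2 * np.power(p, r)
    if convention == "half":
        base = base / 2
    elif convention != "full":
        raise ValueError("convention must be 'half' or 'full'")
    return base if base.ndim else float(base)


def stick_mld(r, tau: float, K: float):
    """Stick-breaking kernel: matches of length r left of a pair at distance tau."""
    r = np.asarray(r, dtype=float)
    if np.any(r >= K):
        raise ValueError("stick_mld requires r < K")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    out = (2 * tau + tau**2 * (K - r)) * np.exp(-tau * r)
    return out if out.ndim else float(out)


def yule_pair_density(tau, params: EvolParams):
    """Pair density of a Yule duplication family after time T.

    (lam K / 2 mu) e^(lam K T) e^(lam K tau / 2 mu) on [0, 2 mu T], else 0.
    """
    lamK = params.lam * params.K
    if lamK <= 0 or params.mu <= 0:
        raise ValueError("lam, K and mu must be positive")
    tau = np.asarray(tau, dtype=float)
    dens = (lamK / (2 * params.mu)) * np.exp(lamK * params.T) * np.exp(
        lamK * tau / (2 * params.mu)
    )
    dens = np.where((tau >= 0) & (tau <= 2 * params.mu * params.T), dens, 0.0)
    return dens if dens.ndim else float(dens)


def yule_density(params: EvolParams) -> PairDensity:
    return PairDensity(
        fn=lambda t: yule_pair_density(t, params),
        support=(0.0, 2 * params.mu * params.T),
        form="analytic-yule",
    )


def retro_pair_shape(s, a: float):
    """Unit-normalized pdf of the scaled distance s = tau/(mu T) of a
    retroduplicant pair: the distribution of (2 - x - y) + a |x - y| for
    x, y iid uniform on [0, 1].

    Triangular: rises as s/(1+a) up to its peak at s = 1+a, falls as
    (2-s)/(1-a), and vanishes at s = 0 and s >= 2.
    """
    if not (0 <= a < 1):
        raise ValueError("a must lie in [0, 1)")
    s = np.asarray(s, dtype=float)
    out = np.where(
        (s >= 0) & (s <= 1 + a),
        s / (1 + a),
        np.where((s > 1 + a) & (s <= 2), (2 - s) / (1 - a), 0.0),
    )
    return out if out.ndim else float(out)


def retro_pair_density(tau, params: EvolParams):
    """Pair density of a retroduplicated pseudogene family after time T.

    Derived from tau = mu (2T - T1 - T2) + a mu |T1 - T2| with T1, T2
    uniform on [0, T]; normalised to (lam K T)^2 / 2 pairs.  Continuous and
    piecewise linear, N(0) = 0, peak at (1+a) mu T, zero beyond 2 mu T.
    """
    muT = params.mu * params.T
    n_pairs = (params.lam * params.K * params.T) ** 2 / 2
    return n_pairs * retro_pair_shape(np.asarray(tau, dtype=float) / muT, params.a) / muT


def retro_density(params: EvolParams) -> PairDensity:
    return PairDensity(
        fn=lambda t: retro_pair_density(t, params),
        support=(0.0, 2 * params.mu * params.T),
        form="analytic-retro",
        total=(params.lam * params.K * params.T) ** 2 / 2,
    )


def convolve_pair_density(
    na: PairDensity, nb: PairDensity, n_grid: int = 4096
) -> PairDensity:
    """Comparative pair density N(tau) = int_0^tau NA(tau - s) NB(s) ds.

    Numeric convolution on a shared grid; the result always vanishes at
    tau = 0 (the integration range is empty there), which is what drives
    the -4 tail of comparative alignments.
    """
    hi = na.support[1] + nb.support[1]
    grid = np.linspace(0.0, hi, n_grid)
    dtau = grid[1] - grid[0]
    fa = na(grid)
    fb = nb(grid)
    conv = np.convolve(fa, fb)[:n_grid] * dtau
    conv[0] = 0.0

    def interp(tau, grid=grid, conv=conv):
        return np.interp(tau, grid, conv)

    total = None
    if na.total is not None and nb.total is not None:
        total = na.total * nb.total
    return PairDensity(fn=interp, support=(0.0, hi), form="analytic-convolution", total=total)


def mld_from_density(r, n: PairDensity, K: float, rtol: float = 1e-6):
    """m(r) = integral of the stick-breaking kernel against N(tau).

    Adaptive quadrature on tau in [0, tau_cut], with tau_cut chosen so the
    exponential kernel has decayed below 1e-12 (or the support ends).
    """
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(r_arr < 1) or np.any(r_arr >= K):
        raise ValueError("mld_from_density requires 1 <= r < K")
    lo = max(n.support[0], 0.0)
    out = np.empty(r_arr.shape)
    for idx, rv in enumerate(r_arr):
        hi = min(n.support[1], lo + 30.0 / rv)
        if hi <= lo:
            out[idx] = 0.0
            continue
        val, _err = integrate.quad(
            lambda t: (2 * t + t * t * (K - rv)) * np.exp(-t * rv) * n(t),
            lo,
            hi,
            epsrel=rtol,
            limit=200,
        )
        out[idx] = val
    return out if np.asarray(r).ndim else float(out[0])


def yule_mld_tail(r, params: EvolParams):
    """Closed-form -3 tail of the Yule family MLD, lam K^2 e^(lam K T)/(mu r^3).

    Valid for lam K/(2 mu) << r < K.
    """
    r = np.asarray(r, dtype=float)
    lamK = params.lam * params.K
    out = params.lam * params.K**2 * np.exp(lamK * params.T) / (params.mu * r**3)
    return out if out.ndim else float(out)


def random_dup_mld_tail(r, params: EvolParams):
    """Stationary random-duplication tail: A L / r^3 with A = lam K / mu."""
    r = np.asarray(r, dtype=float)
    out = params.A * params.L / r**3
    return out if out.ndim else float(out)


def retro_mld_tail(r, params: EvolParams):
    """Retroduplication family tail: 3 K^3 lam^2 / ((1+a) mu^2) r^-4."""
    r = np.asarray(r, dtype=float)
    out = 3 * params.K**3 * params.lam**2 / ((1 + params.a) * params.mu**2) / r**4
    return out if out.ndim else float(out)


def comparative_mld_tail(r, dndtau0: float, K: float):
    """Comparative tail N'(0) (6K - 2r)/r^4 from the linear term of N(tau)."""
    r = np.asarray(r, dtype=float)
    out = dndtau0 * (6 * K - 2 * r) / r**4
    return out if out.ndim else float(out)


def rmax(A: float, L: float, K: float) -> float:
    """Longest expected exact match under neutral duplication: (A L)^(1/3), capped at K."""
    return float(min((A * L) ** (1.0 / 3.0), K))


def exponent_from_beta(beta: float) -> float:
    """Tail exponent alpha = -(3 + beta) when N(tau) ~ tau^beta near 0."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    return -(3.0 + beta)
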