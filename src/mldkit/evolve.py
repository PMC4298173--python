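"""Kinetic Monte Carlo simulation of genome evolution by mutation and
duplication.

Two independent Poisson processes act on a sequence of length L: point
mutations (rate mu per bp; an effective rate, since short indels destroy
exact matches just like substitutions) and segmental duplications (rate
lam per bp).  Between consecutive duplication events the mutation process
factorises over sites, so mutations are applied in exact vectorised
batches: per site the number of hits in an interval is Poisson, and a site
hit k times ends up unchanged with probability 1/4 + (3/4)(-1/3)^k (the
k-step uniform-replacement chain), otherwise uniformly one of the other
three bases.  This reproduces exact Gillespie dynamics at a fraction of
the cost.

Three duplication modes are provided:

* ``random-dup`` -- copy a random K-mer over another random K-mer position,
  keeping L constant (the stationary self-alignment MLD has a -3 tail);
* ``yule``       -- a family of segments in which every segment duplicates
  at rate lam*K, appended at the end (-3 tail);
* ``retro``      -- a single source gene of length K duplicates at rate
  lam*K; copies never duplicate and the source mutates at the reduced rate
  a*mu (the copy-family MLD has a -4 tail).

A speciation protocol duplicates a stationary ancestor and evolves the two
descendants independently under region-wise heterogeneous mutation rates
(region length M, rates mu * Exponential(mean 1)), producing the -4 tail
of comparative alignments of diverged species.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import mems
from .sequences import Sequence

_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

__all__ = [
    "SimConfig",
    "random_codes",
    "codes_to_sequence",
    "evolve_sequence",
    "evolve_yule",
    "evolve_retro",
    "make_rate_field",
    "stationary_sequence",
    "speciate_and_diverge",
    "simulate_divergence_pair",
    "self_mld_ensemble",
    "retro_family_mld",
    "comparative_mld_ensemble",
]


@dataclass
class SimConfig:
    """Parameters of the evolution simulator (rates per unit time, bp units)."""

    L: int = 100_000
    mu: float = 1.0
    lam: float = 1e-3
    K: int = 1000
    mode: str = "random-dup"
    a: float = 0.1
    M: int = 1000
    t1: float = 2.0
    t_burnin: float = 5.0
    post_split_lam: float = 0.0

    def __post_init__(self) -> None:
        if self.K > self.L:
            raise ValueError("duplication length K must not exceed L")
        if self.mode not in ("random-dup", "yule", "retro"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0 <= self.a < 1):
            raise ValueError("source-gene rate ratio a must lie in [0, 1)")
        for name in ("mu", "lam", "t1", "t_burnin"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def random_codes(L: int, rng: np.random.Generator) -> np.ndarray:
    """An iid uniform sequence as base codes 0..3."""
    return rng.integers(0, 4, L, dtype=np.uint8)


def codes_to_sequence(codes: np.ndarray, id: str = "sim") -> Sequence:
    return Sequence(id=id, bases=_CODE_TO_BASE[codes].tobytes().decode("ascii"))


def _apply_hits(codes: np.ndarray, positions: np.ndarray, rng) -> int:
    """Apply point-mutation hits at (possibly repeated) positions, exactly.

    Conditional on being hit k times a site stays unchanged with
    probability 1/4 + (3/4)(-1/3)^k, else becomes one of the other three
    bases uniformly.
    """
    if positions.size == 0:
        return 0
    pos, cnt = np.unique(positions, return_counts=True)
    p_same = 0.25 + 0.75 * np.power(-1.0 / 3.0, cnt)
    moved = pos[rng.random(pos.size) >= p_same]
    if moved.size:
        shift = rng.integers(1, 4, moved.size).astype(np.uint8)
        codes[moved] = (codes[moved] + shift) % 4
    return int(positions.size)


def _mutate_uniform(codes, lo: int, hi: int, mu: float, dt: float, rng) -> int:
    """One exact mutation batch at uniform rate mu on codes[lo:hi]."""
    span = hi - lo
    if span <= 0 or mu <= 0 or dt <= 0:
        return 0
    n = rng.poisson(span * mu * dt)
    if n == 0:
        return 0
    return _apply_hits(codes, lo + rng.integers(0, span, n), rng)


def _mutate_regional(codes, rates: np.ndarray, M: int, dt: float, rng) -> int:
    """One exact mutation batch with one rate per M-bp region."""
    L = codes.size
    starts = np.arange(0, L, M, dtype=np.int64)
    lens = np.minimum(M, L - starts)
    counts = rng.poisson(lens * rates * dt)
    total = int(counts.sum())
    if total == 0:
        return 0
    rep_starts = np.repeat(starts, counts)
    rep_lens = np.repeat(lens, counts)
    positions = rep_starts + (rng.random(total) * rep_lens).astype(np.int64)
    return _apply_hits(codes, positions, rng)


def evolve_sequence(
    start: np.ndarray | Sequence,
    config: SimConfig,
    duration: float,
    rng: np.random.Generator,
    rates: np.ndarray | None = None,
    return_counts: bool = False,
):
    """Evolve a fixed-length sequence under mutation + random duplication.

    ``rates`` (one per M-bp region) switches on heterogeneous mutation;
    otherwise the uniform rate ``config.mu`` applies.  Duplications copy a
    K-mer starting at a uniform locus c over the K-mer at a uniform locus
    v (source read before paste), keeping L constant.
    """
    if isinstance(start, Sequence):
        codes = np.frombuffer(start.bases.encode("ascii"), dtype=np.uint8)
        lut = np.zeros(256, dtype=np.uint8)
        lut[np.frombuffer(b"ACGT", dtype=np.uint8)] = np.arange(4, dtype=np.uint8)
        codes = lut[codes].copy()
        decode = True
    else:
        codes = np.array(start, dtype=np.uint8, copy=True)
        decode = False
    L = codes.size
    if config.K > L:
        raise ValueError("duplication length K exceeds sequence length")
    n_mut = 0
    n_dup = rng.poisson(config.lam * L * duration) if config.lam > 0 and duration > 0 else 0
    times = np.sort(rng.random(n_dup) * duration) if n_dup else np.empty(0)
    t_prev = 0.0
    for t in list(times) + [duration]:
        dt = t - t_prev
        if rates is None:
            n_mut += _mutate_uniform(codes, 0, L, config.mu, dt, rng)
        else:
            n_mut += _mutate_regional(codes, rates, config.M, dt, rng)
        if t < duration:
            c, v = rng.integers(0, L - config.K + 1, 2)
            codes[v : v + config.K] = codes[c : c + config.K].copy()
        t_prev = t
    result = codes_to_sequence(codes) if decode else codes
    if return_counts:
        return result, {"mutations": n_mut, "duplications": int(n_dup)}
    return result


def _grow(buf: np.ndarray, needed: int) -> np.ndarray:
    if needed <= buf.size:
        return buf
    new = np.empty(max(needed, 2 * buf.size), dtype=np.uint8)
    new[: buf.size] = buf
    return new


def evolve_yule(config: SimConfig, duration: float, rng) -> np.ndarray:
    """Grow a Yule segment family; n segments occupy [0, n*K) at the end.

    Starts from one random segment of length K; each extant segment
    duplicates at rate lam*K and the copy is appended after position n*K.
    """
    K = config.K
    lamK = config.lam * K
    buf = _grow(np.empty(0, dtype=np.uint8), 16 * K)
    buf[:K] = random_codes(K, rng)
    n = 1
    t = 0.0
    while True:
        dt = rng.exponential(1.0 / (n * lamK)) if lamK > 0 else np.inf
        if t + dt >= duration:
            _mutate_uniform(buf, 0, n * K, config.mu, duration - t, rng)
            return buf[: n * K].copy()
        _mutate_uniform(buf, 0, n * K, config.mu, dt, rng)
        s = int(rng.integers(n))
        buf = _grow(buf, (n + 1) * K)
        buf[n * K : (n + 1) * K] = buf[s * K : (s + 1) * K].copy()
        n += 1
        t += dt


def evolve_retro(config: SimConfig, duration: float, rng) -> np.ndarray:
    """Grow a retroduplicated pseudogene family.

    The source gene at [0, K) duplicates at rate lam*K and mutates at the
    reduced rate a*mu; every copy is appended at n*K, mutates at mu and
    never duplicates.  The copy family is the slice [K:] of the result.
    """
    K = config.K
    lamK = config.lam * K
    buf = _grow(np.empty(0, dtype=np.uint8), 16 * K)
    buf[:K] = random_codes(K, rng)
    n = 1
    t = 0.0

    def mutate(dt: float) -> None:
        _mutate_uniform(buf, 0, K, config.a * config.mu, dt, rng)
        _mutate_uniform(buf, K, n * K, config.mu, dt, rng)

    while True:
        dt = rng.exponential(1.0 / lamK) if lamK > 0 else np.inf
        if t + dt >= duration:
            mutate(duration - t)
            return buf[: n * K].copy()
        mutate(dt)
        buf = _grow(buf, (n + 1) * K)
        buf[n * K : (n + 1) * K] = buf[0:K].copy()
        n += 1
        t += dt


def make_rate_field(config: SimConfig, rng) -> np.ndarray:
    """One mutation rate per M-bp region: mu times Exponential(mean 1)."""
    n_regions = int(np.ceil(config.L / config.M))
    return config.mu * rng.exponential(1.0, n_regions)


def stationary_sequence(
    config: SimConfig, rng, rates: np.ndarray | None = None
) -> np.ndarray:
    """An equilibrated genome: iid start evolved for t_burnin time units.

    With unit mean mutation rate the default burn-in of 5 corresponds to 5
    expected substitutions per site, well past the relaxation time of the
    match content at the lengths analysed (a match of length r decays at
    rate ~ 2 mu r >> 1/5 for r >= 20).
    """
    codes = random_codes(config.L, rng)
    return evolve_sequence(codes, config, config.t_burnin, rng, rates=rates)


def speciate_and_diverge(
    ancestor: np.ndarray,
    config: SimConfig,
    rng,
    rates_a: np.ndarray | None = None,
    rates_b: np.ndarray | None = None,
):
    """Duplicate a genome and evolve the two copies independently for t1.

    Each descendant receives its own freshly drawn heterogeneous rate
    field (regions of length M, rates mu * Exp(1)).  Segmental
    duplications run at ``post_split_lam`` during the divergence phase,
    zero by default: at the stationary-state rate (lam*K per site and unit
    time) ongoing pastes would overwrite the conserved orthologous
    segments faster than slow mutation can preserve them, leaving no
    comparative tail at all; the conserved-element regime requires the
    post-split dynamics to be dominated by point mutations.
    """
    if rates_a is None:
        rates_a = make_rate_field(config, rng)
    if rates_b is None:
        rates_b = make_rate_field(config, rng)
    post_cfg = replace(config, lam=config.post_split_lam)
    a = evolve_sequence(ancestor, post_cfg, config.t1, rng, rates=rates_a)
    b = evolve_sequence(ancestor, post_cfg, config.t1, rng, rates=rates_b)
    return (a, rates_a), (b, rates_b)


@dataclass
class DivergencePair:
    codes_a: np.ndarray
    codes_b: np.ndarray
    rates_a: np.ndarray
    rates_b: np.ndarray


def simulate_divergence_pair(config: SimConfig, rng) -> DivergencePair:
    """Full two-species protocol: heterogeneous-rate ancestor evolved to
    stationarity, whole-genome duplication (speciation), then independent
    divergence of A and B for t1 under fresh rate fields."""
    rates_anc = make_rate_field(config, rng)
    ancestor = stationary_sequence(config, rng, rates=rates_anc)
    (a, ra), (b, rb) = speciate_and_diverge(ancestor, config, rng)
    return DivergencePair(codes_a=a, codes_b=b, rates_a=ra, rates_b=rb)


# ---------------------------------------------------------------------------
# Ensemble pipelines (pooled MLDs over independent replicates)

def self_mld_ensemble(
    config: SimConfig, n_reps: int, rng, minlen: int = mems.DEFAULT_MINLEN
) -> mems.MLD:
    """Pooled self-alignment MLD of independent stationary genomes."""
    pooled = mems.MLD()
    for _ in range(n_reps):
        codes = stationary_sequence(config, rng)
        matches = mems.find_self_mems(codes_to_sequence(codes), minlen=minlen)
        pooled = pooled + mems.mld_histogram(matches)
    return pooled


def retro_family_mld(
    config: SimConfig,
    duration: float,
    n_reps: int,
    rng,
    minlen: int = mems.DEFAULT_MINLEN,
) -> mems.MLD:
    """Pooled self-alignment MLD of the copy families (source excluded)."""
    pooled = mems.MLD()
    for _ in range(n_reps):
        codes = evolve_retro(config, duration, rng)
        copies = codes[config.K :]
        if copies.size == 0:
            continue
        matches = mems.find_self_mems(codes_to_sequence(copies), minlen=minlen)
        pooled = pooled + mems.mld_histogram(matches)
    return pooled


def comparative_mld_ensemble(
    config: SimConfig, n_reps: int, rng, minlen: int = mems.DEFAULT_MINLEN
) -> mems.MLD:
    """Pooled comparative MLD over independently diverged genome pairs."""
    pooled = mems.MLD()
    for _ in range(n_reps):
        pair = simulate_divergence_pair(config, rng)
        matches = mems.find_mems(
            codes_to_sequence(pair.codes_a),
            codes_to_sequence(pair.codes_b),
            minlen=minlen,
        )
        pooled = pooled + mems.mld_histogram(matches)
    return pooled
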