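"""Tree-level samplers of pairwise evolutionary distances, and the
pseudogene ranking utility.

These samplers generate the pair densities N(tau) directly at the level of
the genealogy, without evolving sequences, and serve as fast Monte Carlo
counterparts of the analytic densities in :mod:`mldkit.models`:

* a Yule family (every segment duplicates at rate lam*K) yields leaf-pair
  distances tau = 2 mu (T - t_MRCA);
* a retroduplicated family (a single slowly evolving source gene, copies
  that never duplicate) yields tau = mu (2T - T1 - T2) + a mu |T1 - T2|
  for retroduplication times T1, T2 uniform on [0, T].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import PairDensity

__all__ = [
    "DistanceSampleSet",
    "simulate_yule_tree",
    "simulate_retro_distances",
    "pair_density_histogram",
    "rank_by_average_distance",
    "read_distance_matrix",
]


@dataclass
class DistanceSampleSet:
    """Pairwise distances tau with multiplicities (weights)."""

    values: np.ndarray
    weights: np.ndarray
    provenance: str
    params: dict = field(default_factory=dict)

    @property
    def n_pairs(self) -> float:
        return float(self.weights.sum())


def simulate_yule_tree(
    lamK: float, mu: float, T: float, rng: np.random.Generator
) -> DistanceSampleSet:
    """Grow one Yule tree for time T and read off all leaf-pair distances.

    Event-driven on the lineage count: with n extant segments the next
    duplication arrives after Exp(n * lamK).  Every branching event at time
    t contributes (left leaves) x (right leaves) pairs whose most recent
    common ancestor sits at t, i.e. tau = 2 mu (T - t) per pair, which is
    recorded as one weighted sample.
    """
    if T <= 0 or lamK <= 0:
        return DistanceSampleSet(
            values=np.empty(0),
            weights=np.empty(0),
            provenance="yule",
            params={"lamK": lamK, "mu": mu, "T": T},
        )
    # Nodes: parent of each node; leaves start as node 0.
    children: list[tuple[int, int] | None] = [None]
    event_time: list[float] = [np.nan]
    leaves = [0]
    t = 0.0
    while True:
        n = len(leaves)
        t += rng.exponential(1.0 / (n * lamK))
        if t >= T:
            break
        k = int(rng.integers(n))
        node = leaves[k]
        left, right = len(children), len(children) + 1
        children.extend([None, None])
        event_time.extend([np.nan, np.nan])
        children[node] = (left, right)
        event_time[node] = t
        leaves[k] = left
        leaves.append(right)
    # Leaf counts bottom-up: children always have larger indices.
    counts = np.ones(len(children), dtype=np.int64)
    taus, weights = [], []
    for node in range(len(children) - 1, -1, -1):
        if children[node] is not None:
            left, right = children[node]
            counts[node] = counts[left] + counts[right]
            taus.append(2.0 * mu * (T - event_time[node]))
            weights.append(counts[left] * counts[right])
    return DistanceSampleSet(
        values=np.asarray(taus, dtype=float),
        weights=np.asarray(weights, dtype=float),
        provenance="yule",
        params={"lamK": lamK, "mu": mu, "T": T, "n_leaves": len(leaves)},
    )


def simulate_retro_distances(
    lamK: float,
    mu: float,
    a: float,
    T: float,
    n_samples: int,
    rng: np.random.Generator,
) -> DistanceSampleSet:
    """Sample pair distances of a retroduplicated family.

    Retroduplication times T1, T2 are uniform on [0, T]; the source gene
    mutates at a*mu between the two events, the copies at mu afterwards.
    (a = 1 is allowed here; the closed-form density requires a < 1.)
    """
    if not (0 <= a <= 1):
        raise ValueError("a must lie in [0, 1]")
    t1 = rng.uniform(0.0, T, n_samples)
    t2 = rng.uniform(0.0, T, n_samples)
    tau = mu * (2 * T - t1 - t2) + a * mu * np.abs(t1 - t2)
    return DistanceSampleSet(
        values=tau,
        weights=np.ones(n_samples),
        provenance="retro",
        params={"lamK": lamK, "mu": mu, "a": a, "T": T},
    )


def pair_density_histogram(samples: DistanceSampleSet, bins) -> PairDensity:
    """Empirical N(tau) from distance samples; integrates to the pair count."""
    counts, edges = np.histogram(samples.values, bins=bins, weights=samples.weights)
    return PairDensity.from_histogram(edges, counts)


def rank_by_average_distance(d: pd.DataFrame | np.ndarray, labels=None) -> list[str]:
    """Order items by their average distance to all others, ascending.

    The diagonal is excluded from the averages; ties are broken by label.
    This is the ranking used to fix the attachment order of a pseudogene
    family tree (the source gene retroduplicates to the closest pseudogene
    first, then the next, and so on).
    """
    if isinstance(d, pd.DataFrame):
        mat = d.to_numpy(dtype=float)
        labels = list(d.index)
    else:
        mat = np.asarray(d, dtype=float)
        labels = list(labels) if labels is not None else [str(i) for i in range(len(mat))]
    n = mat.shape[0]
    if mat.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if n < 2:
        return labels
    means = (mat.sum(axis=1) - np.diag(mat)) / (n - 1)
    order = sorted(range(n), key=lambda i: (means[i], labels[i]))
    return [labels[i] for i in order]


def read_distance_matrix(path) -> pd.DataFrame:
    """Read a square distance matrix: labelled TSV or PHYLIP square format."""
    with open(path) as fh:
        first = fh.readline().split()
    if len(first) == 1 and first[0].isdigit():
        n = int(first[0])
        df = pd.read_csv(
            path, sep=r"\s+", skiprows=1, header=None, index_col=0, nrows=n
        )
        df.columns = list(df.index)
        return df
    return pd.read_csv(path, sep="\t", index_col=0)
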