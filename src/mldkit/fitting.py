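"""Tail definition and power-law exponent estimation for MLDs.

The "tail" of an MLD starts where chance matches of iid sequences become
negligible (expected count below one half); beyond it, the models predict
m(r) ~ r^alpha.  The exponent is estimated, as in the usual graphical
practice, by weighted least squares of log density against log length on
logarithmically binned counts, with Poisson weights (the variance of the
log of a count n is approximately 1/n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .mems import LogBinnedMLD

__all__ = ["TailFit", "InsufficientDataError", "tail_start", "fit_tail_exponent", "loglog_slope"]


class InsufficientDataError(ValueError):
    """Raised when too few occupied bins exist to estimate an exponent."""


@dataclass
class TailFit:
    exponent: float
    stderr: float
    r_lo: float
    r_hi: float
    n_matches_in_tail: int
    method: str = "wls-logbin"


def tail_start(
    L_a: float,
    L_b: float | None = None,
    p: float = 0.25,
    convention: str = "half",
    min_r: int = 1,
) -> int:
    """Smallest length at which the iid expectation drops below 0.5.

    For Gbp-scale genomes at p = 1/4 this lands near 30 bp, just past the
    classic "matches longer than 25 bp are not expected by chance" mark.
    """
    if L_b is None:
        L_b = L_a
    prefactor = L_a * L_b * (1 - p) ** 2
    if convention == "half":
        prefactor /= 2
    elif convention != "full":
        raise ValueError("convention must be 'half' or 'full'")
    if prefactor <= 0 or p <= 0:
        return min_r
    # prefactor * p^r < 1/2  <=>  r > log(0.5/prefactor)/log(p)
    r = math.floor(math.log(0.5 / prefactor) / math.log(p)) + 1
    return max(min_r, r)


def fit_tail_exponent(
    binned: LogBinnedMLD,
    r_lo: float | None = None,
    r_hi: float | None = None,
    min_count_top: int = 5,
) -> TailFit:
    """Weighted least-squares slope of log(density) vs log(mean length).

    Occupied bins with mean length in [r_lo, r_hi] enter with weight equal
    to their match count.  ``r_hi`` defaults to the last bin holding at
    least ``min_count_top`` matches, suppressing the noisy extreme tip.
    At least 4 occupied bins are required.
    """
    occ = binned.occupied
    if r_hi is None:
        eligible = [b.mean_r for b in occ if b.count >= min_count_top]
        r_hi = max(eligible) if eligible else 0.0
    if r_lo is None:
        r_lo = occ[0].mean_r if occ else 0.0
    sel = [b for b in occ if r_lo <= b.mean_r <= r_hi]
    if len(sel) < 4:
        raise InsufficientDataError(
            f"only {len(sel)} occupied bins in [{r_lo:g}, {r_hi:g}]; need >= 4"
        )
    x = np.log([b.mean_r for b in sel])
    y = np.log([b.density for b in sel])
    w = np.array([b.count for b in sel], dtype=float)
    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    return TailFit(
        exponent=float(res.params[1]),
        stderr=float(res.bse[1]),
        r_lo=float(r_lo),
        r_hi=float(r_hi),
        n_matches_in_tail=int(w.sum()),
    )


def loglog_slope(r: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Unweighted log-log regression slope (for smooth model curves)."""
    r = np.asarray(r, dtype=float)
    y = np.asarray(y, dtype=float)
    res = sm.OLS(np.log(y), sm.add_constant(np.log(r))).fit()
    return float(res.params[1]), float(res.bse[1])
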