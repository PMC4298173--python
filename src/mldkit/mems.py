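"""Maximal exact match enumeration and match length distributions (MLDs).

The MLD of a self- or comparative alignment is the histogram m(r) counting
maximal exact matches of length r.  Long matches (beyond what iid chance
produces) carry the signal of duplication history, so the representation of
choice is a logarithmically binned density whose power-law tail exponent is
estimated downstream (see :mod:`mldkit.fitting`).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from . import suffix
from .sequences import Sequence, reverse_complement

DEFAULT_MINLEN = 20
FORMAT_TAG = "mldkit-tsv-1"


class Match(NamedTuple):
    """A maximal exact match; 0-based, half-open [pos, pos+length)."""

    pos_a: int
    pos_b: int
    length: int
    strand: str = "+"


@dataclass
class MLD:
    """Histogram of match lengths: counts[r] = number of matches of length r."""

    counts: dict[int, int] = field(default_factory=dict)

    @property
    def total_matches(self) -> int:
        return sum(self.counts.values())

    @property
    def max_length(self) -> int:
        return max(self.counts) if self.counts else 0

    def __add__(self, other: "MLD") -> "MLD":
        merged = Counter(self.counts)
        merged.update(other.counts)
        return MLD(dict(merged))

    def to_frame(self) -> pd.DataFrame:
        rs = sorted(self.counts)
        return pd.DataFrame({"r": rs, "count": [self.counts[r] for r in rs]})


class LogBin(NamedTuple):
    lo: int
    hi: int
    mean_r: float
    count: int
    density: float


@dataclass
class LogBinnedMLD:
    """Geometric binning of an MLD; density is matches per unit length."""

    bins: list[LogBin]
    ratio: float
    total_matches: int

    @property
    def occupied(self) -> list[LogBin]:
        return [b for b in self.bins if b.count > 0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bins, columns=LogBin._fields)


def _as_bases(seq: Sequence | str) -> str:
    return seq.bases if isinstance(seq, Sequence) else seq


def find_mems(
    a: Sequence | str,
    b: Sequence | str,
    minlen: int = DEFAULT_MINLEN,
    revcomp: bool = False,
) -> list[Match]:
    """All maximal exact matches of length >= minlen between a and b.

    Forward strand by default; with ``revcomp`` the reverse complement of b
    is additionally searched, matches being reported with forward-strand b
    coordinates and strand '-'.  No match spans an N.  All occurrences are
    reported regardless of uniqueness (apply :func:`filter_unique` to mimic
    the uniqueness filter).
    """
    bases_a, bases_b = _as_bases(a), _as_bases(b)
    out = _cross_mems(bases_a, bases_b, minlen, "+")
    if revcomp:
        rc = reverse_complement(Sequence(id="", bases=bases_b)).bases
        lb = len(bases_b)
        out.extend(
            Match(m.pos_a, lb - m.pos_b - m.length, m.length, "-")
            for m in _cross_mems(bases_a, rc, minlen, "-")
        )
    return out


def _cross_mems(bases_a: str, bases_b: str, minlen: int, strand: str) -> list[Match]:
    if not bases_a or not bases_b:
        return []
    codes, starts = suffix.encode_concat([bases_a, bases_b])
    len_a = len(bases_a)
    b_start = starts[1]
    out = []
    for i, j, length in suffix.maximal_match_pairs(codes, minlen):
        i, j = (i, j) if i < j else (j, i)
        if i < len_a and j >= b_start:
            out.append(Match(i, j - b_start, length, strand))
    return out


def find_self_mems(a: Sequence | str, minlen: int = DEFAULT_MINLEN) -> list[Match]:
    """Maximal matches of a sequence against itself.

    The identity diagonal is excluded and each unordered pair of loci is
    reported once, with pos_a < pos_b.
    """
    bases = _as_bases(a)
    if not bases:
        return []
    codes, _ = suffix.encode_concat([bases])
    out = []
    for i, j, length in suffix.maximal_match_pairs(codes, minlen):
        i, j = (i, j) if i < j else (j, i)
        out.append(Match(i, j, length))
    return out


def mld_histogram(matches: Iterable[Match]) -> MLD:
    return MLD(dict(Counter(m.length for m in matches)))


def log_bin(mld: MLD, ratio: float = 1.25, start: int | None = None) -> LogBinnedMLD:
    """Geometric binning with integer bin edges.

    Edges grow by ``ratio`` (snapped up to the next integer so that each
    bin covers a whole number of lengths); density = count / (hi - lo), so
    that sum(density * width) over bins reproduces the total match count
    exactly.
    """
    if ratio <= 1:
        raise ValueError("bin ratio must be > 1")
    if not mld.counts:
        return LogBinnedMLD(bins=[], ratio=ratio, total_matches=0)
    lo = int(start) if start is not None else min(mld.counts)
    top = mld.max_length
    bins: list[LogBin] = []
    while lo <= top:
        hi = max(lo + 1, int(np.ceil(lo * ratio)))
        count = sum(c for r, c in mld.counts.items() if lo <= r < hi)
        width = hi - lo
        bins.append(LogBin(lo, hi, float(np.sqrt(lo * hi)), count, count / width))
        lo = hi
    return LogBinnedMLD(bins=bins, ratio=ratio, total_matches=sum(b.count for b in bins))


def filter_unique(
    matches: list[Match],
    a: Sequence | str,
    b: Sequence | str | None = None,
    share_threshold: int = 20,
) -> list[Match]:
    """Keep only matches whose sequence is unique among all match sequences.

    A match is non-unique if its sequence shares a continuous exact segment
    of more than ``share_threshold`` bp (i.e. >= share_threshold + 1) with
    the sequence of any other match, assessed by an all-vs-all maximal
    match search among the extracted match strings.
    """
    if len(matches) <= 1:
        return list(matches)
    bases_a = _as_bases(a)
    strings = [bases_a[m.pos_a : m.pos_a + m.length] for m in matches]
    codes, starts = suffix.encode_concat(strings)
    starts_arr = np.asarray(starts, dtype=np.int64)
    nonunique: set[int] = set()
    for i, j, _length in suffix.maximal_match_pairs(codes, share_threshold + 1):
        si = int(np.searchsorted(starts_arr, i, side="right")) - 1
        sj = int(np.searchsorted(starts_arr, j, side="right")) - 1
        if si != sj:
            nonunique.add(si)
            nonunique.add(sj)
    return [m for k, m in enumerate(matches) if k not in nonunique]


# ---------------------------------------------------------------------------
# TSV input/output

def _header(kind: str, **params) -> str:
    items = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# {FORMAT_TAG} {kind} {items}".rstrip()


def write_mld_tsv(mld: MLD, path, **params) -> None:
    with open(path, "w") as fh:
        fh.write(_header("mld", **params) + "\n")
        fh.write("r\tcount\n")
        for r in sorted(mld.counts):
            fh.write(f"{r}\t{mld.counts[r]}\n")


def read_mld_tsv(path) -> MLD:
    df = pd.read_csv(path, sep="\t", comment="#")
    return MLD({int(r): int(c) for r, c in zip(df["r"], df["count"]) if c})


def write_binned_tsv(binned: LogBinnedMLD, path, **params) -> None:
    with open(path, "w") as fh:
        fh.write(_header("binned-mld", ratio=binned.ratio, **params) + "\n")
        fh.write("lo\thi\tmean_r\tdensity\n")
        for b in binned.bins:
            fh.write(f"{b.lo}\t{b.hi}\t{b.mean_r:.6g}\t{b.density:.10g}\n")


def write_matches_tsv(
    matches: list[Match], a: Sequence, b: Sequence, path, **params
) -> None:
    """Matches as TSV (seq_a_id, pos_a, seq_b_id, pos_b, length [, strand])."""
    with open(path, "w") as fh:
        fh.write(_header("matches", **params) + "\n")
        fh.write("seq_a_id\tpos_a\tseq_b_id\tpos_b\tlength\tstrand\n")
        for m in matches:
            ida, pa = a.locate(m.pos_a)
            idb, pb = b.locate(m.pos_b)
            fh.write(f"{ida}\t{pa}\t{idb}\t{pb}\t{m.length}\t{m.strand}\n")
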