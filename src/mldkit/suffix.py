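"""Suffix-array machinery behind the maximal exact match (MEM) enumerator.

A MEM between two texts (or two loci of the same text) is an identical
substring pair that cannot be extended on either side.  We enumerate them
from the LCP structure of a suffix array: every pair of suffixes whose
longest common prefix is at least ``minlen`` and whose *preceding*
characters differ corresponds to exactly one MEM, whose length is the LCP
of the two suffixes (right-maximality is automatic, left-maximality is the
preceding-character condition).

Ambiguous bases (``N``) and record separators must never match anything,
not even another ``N``.  This is implemented by encoding every such symbol
as its own unique integer, so equality comparisons against it always fail
and no match can span it.
"""

from __future__ import annotations

import numpy as np

# A, C, G, T get the four small codes; everything else becomes a unique
# non-matching symbol (assigned in encode_concat).
_LUT = np.full(256, -1, dtype=np.int64)
for _i, _c in enumerate(b"ACGT"):
    _LUT[_c] = _i


def encode_concat(parts: list[str]) -> tuple[np.ndarray, list[int]]:
    """Encode DNA strings into one integer array with non-matching joints.

    Parts are concatenated with a single separator symbol between them.
    Returns ``(codes, starts)`` where ``starts[k]`` is the offset of part
    ``k`` inside ``codes``.  Each separator and each non-ACGT base gets a
    unique integer >= 4 so that it is equal to nothing, itself included.
    """
    starts: list[int] = []
    chunks: list[np.ndarray] = []
    sep = np.array([-1], dtype=np.int64)
    pos = 0
    for k, part in enumerate(parts):
        if k > 0:
            chunks.append(sep)
            pos += 1
        starts.append(pos)
        arr = np.frombuffer(part.encode("ascii"), dtype=np.uint8)
        chunks.append(_LUT[arr])
        pos += arr.size
    codes = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
    blocked = codes < 0
    n_blocked = int(blocked.sum())
    if n_blocked:
        codes[blocked] = 4 + np.arange(n_blocked, dtype=np.int64)
    return codes, starts


def suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), numpy lexsort)."""
    n = codes.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    _, rank = np.unique(codes, return_inverse=True)
    rank = rank.astype(np.int64)
    k = 1
    while rank.max() != n - 1:
        second = np.full(n, -1, dtype=np.int64)
        second[: n - k] = rank[k:]
        order = np.lexsort((second, rank))
        changed = (rank[order[1:]] != rank[order[:-1]]) | (
            second[order[1:]] != second[order[:-1]]
        )
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.concatenate(([0], np.cumsum(changed)))
        rank = new_rank
        k *= 2
    sa = np.empty(n, dtype=np.int64)
    sa[rank] = np.arange(n, dtype=np.int64)
    return sa


def lcp_array(codes: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """Kasai's algorithm; lcp[r] = LCP(suffix sa[r-1], suffix sa[r])."""
    n = sa.size
    lcp = [0] * n
    rank = [0] * n
    sal = sa.tolist()
    tl = codes.tolist()
    for r, i in enumerate(sal):
        rank[i] = r
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sal[r - 1]
            while i + h < n and j + h < n and tl[i + h] == tl[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return np.asarray(lcp, dtype=np.int64)


def maximal_match_pairs(codes: np.ndarray, minlen: int) -> list[tuple[int, int, int]]:
    """All left- and right-maximal matching position pairs of length >= minlen.

    Returns tuples ``(i, j, length)`` with text positions ``i != j`` (each
    unordered pair reported once, in suffix-array order).  The caller is
    responsible for mapping positions back to the underlying sequences.
    """
    if minlen < 1:
        raise ValueError("minlen must be >= 1")
    n = codes.size
    if n == 0 or minlen > n:
        return []
    sa = suffix_array(codes)
    lcp = lcp_array(codes, sa)
    hits = np.flatnonzero(lcp >= minlen)
    if hits.size == 0:
        return []
    # Group consecutive SA ranks sharing lcp >= minlen into blocks; every
    # pair inside a block shares a prefix of length min(lcp over the span).
    gaps = np.flatnonzero(np.diff(hits) > 1)
    run_starts = np.concatenate(([0], gaps + 1))
    run_ends = np.concatenate((gaps, [hits.size - 1]))
    sal = sa.tolist()
    lcpl = lcp.tolist()
    tl = codes.tolist()
    out: list[tuple[int, int, int]] = []
    for s_i, e_i in zip(run_starts, run_ends):
        lo = int(hits[s_i]) - 1          # first suffix rank of the block
        hi = int(hits[e_i])              # last suffix rank of the block
        block = sal[lo : hi + 1]
        m = len(block)
        for p in range(m - 1):
            i = block[p]
            ci = tl[i - 1] if i > 0 else -1
            cur = None
            for q in range(p + 1, m):
                v = lcpl[lo + q]
                if cur is None or v < cur:
                    cur = v
                j = block[q]
                if i > 0 and j > 0 and ci == tl[j - 1]:
                    continue  # not left-maximal: both preceded by same symbol
                out.append((i, j, cur))
    return out
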